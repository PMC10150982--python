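"""Predicted-age maturity scoring of syllable renditions.

A small feedforward regressor maps a rendition's latent coordinates to a
"predicted age" in days post hatch — a data-driven maturity score.  Training
minimizes squared prediction error plus an L2 penalty on connection weights
(the penalty weight is chosen on an internal validation split from a small
grid), using full-batch L-BFGS with early stopping once the internal test
split stops improving for three consecutive iterations.

Architecture presets (hidden tanh layers; sizes for 32-d latent input give
the canonical parameter counts of this model family):

    pyramid   32-16-8-4-1   705 parameters
    shallow   32-16-4-1     601 parameters
    linear    32-1          (ordinary least squares function class)

Permutation controls: ``shuffle_mse`` re-scores the held-out split after
permuting production ages relative to latents, either freely ("total") or
only among same-day renditions ("within_day"); the within-day null isolates
sub-circadian structure in the maturity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._nn import MLP

__all__ = [
    "MaturityModel",
    "ShuffleReport",
    "split_dataset",
    "train_age_net",
    "predict_age",
    "shuffle_mse",
    "AGE_ARCHITECTURES",
]

AGE_ARCHITECTURES = {"pyramid": [16, 8, 4], "shallow": [16, 4], "linear": []}
DEFAULT_L2_GRID = (1e-6, 1e-4, 1e-2)
EVAL_AGE_LIMITS = (60.0, 95.0)


def split_dataset(df: pd.DataFrame, eval_fraction: float = 0.2, seed: int = 0):
    """Random disjoint, exhaustive (train, eval) partition of a rendition table."""
    n = len(df)
    if n < 10:
        raise ValueError(f"dataset of {n} renditions is too small to split for training")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_eval = int(round(eval_fraction * n))
    eval_idx = np.sort(perm[:n_eval])
    train_idx = np.sort(perm[n_eval:])
    return df.iloc[train_idx].reset_index(drop=True), df.iloc[eval_idx].reset_index(drop=True)


@dataclass
class MaturityModel:
    """Trained latent -> predicted-age regressor (a pure function of input)."""

    mlp: MLP
    architecture: str
    l2_weight: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def param_count(self) -> int:
        return self.mlp.n_params

    def predict(self, latents: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(latents, dtype=float))
        if x.shape[1] != self.mlp.n_in:
            raise ValueError(f"latent dimension {x.shape[1]} != model input {self.mlp.n_in}")
        out = self.mlp.forward((x - self.x_mean) / self.x_sd).ravel()
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("maturity model produced non-finite predictions")
        return out


def _fit_once(x, y, x_test, y_test, hidden, l2, seed, max_iter, patience):
    """One L-BFGS fit with patience-based early stopping on the test split."""
    rng = np.random.default_rng(seed)
    mlp = MLP(x.shape[1], list(hidden), 1, activation="tanh").init(rng)
    mlp.biases[-1][:] = y.mean()  # start at the constant predictor
    n = x.shape[0]

    def loss_grad(theta):
        mlp.set_flat(theta)
        cache: list = []
        pred = mlp.forward(x, cache).ravel()
        resid = pred - y
        loss = float(resid @ resid) / n + l2 * mlp.weight_sq_sum()
        gw, gb = mlp.backward(cache, (2.0 / n) * resid[:, None])
        for gwi, w in zip(gw, mlp.weights):
            gwi += 2.0 * l2 * w
        g = np.concatenate([np.concatenate([a.ravel(), b]) for a, b in zip(gw, gb)])
        return loss, g

    state = {"best_mse": np.inf, "best_theta": mlp.get_flat(), "since": 0, "iters": 0}

    def callback(theta):
        state["iters"] += 1
        mlp.set_flat(theta)
        mse = float(np.mean((mlp.forward(x_test).ravel() - y_test) ** 2))
        if mse < state["best_mse"] - 1e-12:
            state["best_mse"], state["best_theta"], state["since"] = mse, theta.copy(), 0
        else:
            state["since"] += 1
            if patience is not None and state["since"] >= patience:
                raise StopIteration

    try:
        res = minimize(loss_grad, mlp.get_flat(), jac=True, method="L-BFGS-B",
                       callback=callback,
                       options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-10})
    except StopIteration:
        res = None
    if patience is None and res is not None:
        # early stopping disabled: keep the converged optimum
        state["best_theta"] = res.x
        state["best_mse"] = np.inf
    mlp.set_flat(state["best_theta"])
    if not np.isfinite(state["best_mse"]):
        # callback never improved: evaluate at the returned point
        state["best_mse"] = float(np.mean((mlp.forward(x_test).ravel() - y_test) ** 2))
    return mlp, state["best_mse"], state["iters"]


def train_age_net(
    train_df: pd.DataFrame,
    architecture: str = "pyramid",
    l2_weight: float | None = None,
    seed: int = 0,
    max_iter: int = 500,
    patience: int | None = 3,
    latent_cols: list[str] | None = None,
) -> MaturityModel:
    """Fit the predicted-age network on the training side of a split.

    Rows are internally re-partitioned 70/15/15 into fitting, test
    (early-stopping) and validation (L2 grid selection) subsets.  When
    ``l2_weight`` is None the penalty is chosen from ``DEFAULT_L2_GRID`` by
    validation MSE; passing a float fixes it.  ``patience=None`` disables
    early stopping (L-BFGS runs to convergence).  Deterministic given ``seed``.
    """
    from .synthetic import latent_columns as _lc

    cols = latent_cols if latent_cols is not None else _lc(train_df)
    x_all = train_df[cols].to_numpy(dtype=float)
    y_all = train_df["age_dph"].to_numpy(dtype=float)
    n = x_all.shape[0]
    if n < 10:
        raise ValueError(f"{n} renditions is too few for a 70/15/15 internal split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_fit = int(round(0.70 * n))
    n_test = int(round(0.15 * n))
    fit_idx, test_idx, val_idx = perm[:n_fit], perm[n_fit : n_fit + n_test], perm[n_fit + n_test :]

    x_mean = x_all[fit_idx].mean(axis=0)
    x_sd = x_all[fit_idx].std(axis=0)
    x_sd[x_sd == 0] = 1.0
    xs = (x_all - x_mean) / x_sd
    hidden = AGE_ARCHITECTURES[architecture] if isinstance(architecture, str) else list(architecture)

    grid = [l2_weight] if l2_weight is not None else list(DEFAULT_L2_GRID)
    best = None
    for l2 in grid:
        mlp, test_mse, iters = _fit_once(
            xs[fit_idx], y_all[fit_idx], xs[test_idx], y_all[test_idx],
            hidden, l2, seed, max_iter, patience,
        )
        val_mse = float(np.mean((mlp.forward(xs[val_idx]).ravel() - y_all[val_idx]) ** 2)) if val_idx.size else test_mse
        if best is None or val_mse < best[0]:
            best = (val_mse, l2, mlp, test_mse, iters)
    val_mse, l2, mlp, test_mse, iters = best
    fit_mse = float(np.mean((mlp.forward(xs[fit_idx]).ravel() - y_all[fit_idx]) ** 2))
    return MaturityModel(
        mlp=mlp, architecture=str(architecture), l2_weight=l2, x_mean=x_mean, x_sd=x_sd,
        metadata={
            "seed": seed, "n_train": n, "train_mse": fit_mse, "test_mse": test_mse,
            "val_mse": val_mse, "l2_grid": grid, "iterations": iters,
            "param_count": mlp.n_params, "optimizer": "l-bfgs",
            "split": "70/15/15",
            "fit_indices": fit_idx, "test_indices": test_idx, "val_indices": val_idx,
        },
    )


def predict_age(model: MaturityModel, latents: np.ndarray) -> np.ndarray:
    """Vectorized predicted age (days) for an array of latent vectors."""
    return model.predict(latents)


def attach_predicted_age(model: MaturityModel, df: pd.DataFrame,
                         latent_cols: list[str] | None = None,
                         column: str = "predicted_age") -> pd.DataFrame:
    """Copy of a rendition table with a predicted-age column appended."""
    from .synthetic import latent_columns as _lc

    cols = latent_cols if latent_cols is not None else _lc(df)
    out = df.copy()
    out[column] = model.predict(df[cols].to_numpy(dtype=float))
    return out


@dataclass
class ShuffleReport:
    """Permutation-null comparison of age-prediction MSE (days^2)."""

    mode: str
    n_permutations: int
    perm_mses: np.ndarray
    unshuffled_mse: float

    @property
    def mean_perm_mse(self) -> float:
        return float(self.perm_mses.mean()) if self.perm_mses.size else np.nan

    @property
    def exceedance_fraction(self) -> float:
        """Share of permutation MSEs strictly greater than the unshuffled MSE."""
        if not self.perm_mses.size:
            return np.nan
        return float(np.mean(self.perm_mses > self.unshuffled_mse))


def shuffle_mse(
    model: MaturityModel,
    eval_df: pd.DataFrame,
    mode: str = "total",
    n_permutations: int = 1000,
    seed: int = 0,
    age_limits: tuple[float, float] | None = EVAL_AGE_LIMITS,
    latent_cols: list[str] | None = None,
) -> ShuffleReport:
    """MSE of the model on the held-out split against a permutation null.

    Evaluation is restricted to ``age_limits`` (default 60-95 dph).  In
    ``within_day`` mode only same-``day_index`` age swaps are allowed; days
    with a single rendition contribute no permutation variability.
    """
    from .synthetic import latent_columns as _lc

    df = eval_df
    if age_limits is not None:
        df = df[(df["age_dph"] >= age_limits[0]) & (df["age_dph"] <= age_limits[1])]
    cols = latent_cols if latent_cols is not None else _lc(df)
    pred = model.predict(df[cols].to_numpy(dtype=float))
    age = df["age_dph"].to_numpy(dtype=float)
    unshuffled = float(np.mean((pred - age) ** 2))
    if n_permutations == 0:
        return ShuffleReport(mode, 0, np.empty(0), unshuffled)
    rng = np.random.default_rng(seed)
    n = age.size
    if mode == "total":
        mses = np.array([
            float(np.mean((pred - age[rng.permutation(n)]) ** 2)) for _ in range(n_permutations)
        ])
    elif mode == "within_day":
        day = df["day_index"].to_numpy()
        groups = [np.flatnonzero(day == d) for d in np.unique(day)]
        mses = np.empty(n_permutations)
        shuffled = age.copy()
        for p in range(n_permutations):
            for g in groups:
                shuffled[g] = age[g[rng.permutation(g.size)]]
            mses[p] = float(np.mean((pred - shuffled) ** 2))
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return ShuffleReport(mode, n_permutations, mses, unshuffled)


def save_model(model: MaturityModel, path: str) -> None:
    """Serialize to <path>.npz (weights) + <path>.json (metadata)."""
    import json

    arrays = {}
    for i, (w, b) in enumerate(zip(model.mlp.weights, model.mlp.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    arrays["x_mean"] = model.x_mean
    arrays["x_sd"] = model.x_sd
    np.savez(path + ".npz", **arrays)
    meta = {
        "format_version": 1, "architecture": model.architecture,
        "l2_weight": model.l2_weight, "n_in": model.mlp.n_in,
        "hidden": list(model.mlp.hidden), "activation": model.mlp.activation,
        "metadata": {k: v for k, v in model.metadata.items()
                     if not isinstance(v, np.ndarray)},
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path: str) -> MaturityModel:
    """Inverse of :func:`save_model`."""
    import json

    with open(path + ".json") as fh:
        meta = json.load(fh)
    data = np.load(path + ".npz")
    mlp = MLP(meta["n_in"], list(meta["hidden"]), 1, activation=meta["activation"])
    i = 0
    while f"w{i}" in data:
        mlp.weights.append(data[f"w{i}"])
        mlp.biases.append(data[f"b{i}"])
        i += 1
    return MaturityModel(
        mlp=mlp, architecture=meta["architecture"], l2_weight=meta["l2_weight"],
        x_mean=data["x_mean"], x_sd=data["x_sd"], metadata=meta["metadata"],
    )
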