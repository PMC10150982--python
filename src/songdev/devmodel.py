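"""Time-varying multivariate Gaussian models of syllable distributions.

A small feedforward network maps a production time, encoded as
``[z-scored age, sin(time of day), cos(time of day)]`` (24 h = 2*pi, so
renditions at the same clock time on different days share the circadian
input), to the parameters of a k-dimensional Gaussian over latent space:

    mu             (k values)
    l              (k(k+1)/2 values, reshaped into lower-triangular L)
    d              (k values)
    Sigma = L L^T + diag(exp(d) + eps)

The ``exp(d) + eps`` diagonal guarantees Sigma is symmetric positive definite
for any network output.  Training minimizes the mean negative log likelihood
of held-in latent observations with mini-batch Adam (lr 1e-3), early stopping
on an internal 80/20 test split with best-checkpoint restore.

Architecture presets are sized to the parameter-count families reported for
this model class (hidden ReLU layers; head sized by k):

    wide      3 x 256 units   (141,089 params at k=6; 143,402 at k=7)
    shallow   2 x 256 units   (75,297 at k=6; 80,180 at k=8)
    narrow64  3 x 64 units    (10,721 at k=6; 11,956 at k=8)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import MLP, Adam

__all__ = [
    "GaussianSnapshot",
    "DevModel",
    "LoglikReport",
    "encode_inputs",
    "nll",
    "train_dev_model",
    "eval_loglik",
    "ARCHITECTURES",
]

ARCHITECTURES = {"wide": [256, 256, 256], "shallow": [256, 256], "narrow64": [64, 64, 64]}
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianSnapshot:
    """One (mu, Sigma) of dimension k, in its Cholesky-plus-diagonal form."""

    mu: np.ndarray
    L: np.ndarray
    d: np.ndarray
    eps: float = 1e-4

    @property
    def k(self) -> int:
        return self.mu.size

    @property
    def Sigma(self) -> np.ndarray:
        diag = np.where(np.isfinite(self.d), np.exp(self.d), 0.0) + self.eps
        return self.L @ self.L.T + np.diag(diag)

    @classmethod
    def from_covariance(cls, mu: np.ndarray, sigma: np.ndarray) -> "GaussianSnapshot":
        """Wrap an explicit SPD covariance (d -> -inf, eps = 0: pure L L^T)."""
        mu = np.asarray(mu, dtype=float)
        return cls(mu=mu, L=np.linalg.cholesky(np.asarray(sigma, dtype=float)),
                   d=np.full(mu.size, -np.inf), eps=0.0)


def encode_inputs(age_dph, time_of_day_h, age_mean: float, age_sd: float) -> np.ndarray:
    """Stack [z_age, sin, cos] network inputs, shape (n, 3)."""
    if age_sd == 0:
        raise ValueError("age SD is zero; cannot z-score production ages")
    age = np.atleast_1d(np.asarray(age_dph, dtype=float))
    tod = np.atleast_1d(np.asarray(time_of_day_h, dtype=float))
    ang = 2.0 * np.pi * tod / 24.0
    return np.column_stack([(age - age_mean) / age_sd, np.sin(ang), np.cos(ang)])


def nll(snapshot: GaussianSnapshot, latent: np.ndarray) -> float | np.ndarray:
    """-log N(latent; mu, Sigma), natural log. Accepts (k,) or (n, k)."""
    x = np.asarray(latent, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != snapshot.k:
        raise ValueError(f"latent dimension {x.shape[1]} != snapshot k={snapshot.k}")
    sigma = snapshot.Sigma
    chol = np.linalg.cholesky(sigma)
    from scipy.linalg import solve_triangular

    y = solve_triangular(chol, (x - snapshot.mu).T, lower=True)
    out = 0.5 * (y * y).sum(axis=0) + np.log(np.diag(chol)).sum() + 0.5 * snapshot.k * _LOG2PI
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class DevModel:
    """Trained density network plus frozen input-normalization constants."""

    mlp: MLP
    k: int
    age_mean: float
    age_sd: float
    eps: float = 1e-4
    architecture: str = "narrow64"
    metadata: dict = field(default_factory=dict)

    @property
    def param_count(self) -> int:
        return self.mlp.n_params

    def _parse(self, out: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n, k = out.shape[0], self.k
        t = k * (k + 1) // 2
        mu = out[:, :k]
        lv = out[:, k : k + t]
        d = out[:, k + t :]
        rows, cols = np.tril_indices(k)
        L = np.zeros((n, k, k))
        L[:, rows, cols] = lv
        return mu, L, d

    def forward_batch(self, age_dph, time_of_day_h) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu, chol(Sigma), log|Sigma|) for a vector of production times."""
        u = encode_inputs(age_dph, time_of_day_h, self.age_mean, self.age_sd)
        out = self.mlp.forward(u)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("density network produced non-finite outputs")
        mu, L, d = self._parse(out)
        sigma = L @ np.swapaxes(L, 1, 2)
        idx = np.arange(self.k)
        sigma[:, idx, idx] += np.exp(d) + self.eps
        chol = np.linalg.cholesky(sigma)
        logdet = 2.0 * np.log(chol[:, idx, idx]).sum(axis=1)
        return mu, chol, logdet

    def snapshot(self, age_dph: float, time_of_day_h: float) -> GaussianSnapshot:
        u = encode_inputs(age_dph, time_of_day_h, self.age_mean, self.age_sd)
        out = self.mlp.forward(u)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("density network produced non-finite outputs")
        mu, L, d = self._parse(out)
        return GaussianSnapshot(mu=mu[0], L=L[0], d=d[0], eps=self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _loss_and_grads(model: DevModel, u: np.ndarray, x: np.ndarray):
    """Mean NLL over a batch and its gradients wrt network parameters."""
    k = model.k
    cache: list = []
    out = model.mlp.forward(u, cache)
    mu, L, d = model._parse(out)
    ed = np.exp(d)
    sigma = L @ np.swapaxes(L, 1, 2)
    idx = np.arange(k)
    sigma[:, idx, idx] += ed + model.eps
    chol = np.linalg.cholesky(sigma)
    logdet = 2.0 * np.log(chol[:, idx, idx]).sum(axis=1)
    delta = x - mu
    sinv = np.linalg.inv(sigma)  # k <= 8: explicit inverse is cheap and exact enough
    sd = np.einsum("nij,nj->ni", sinv, delta)
    nll_vec = 0.5 * logdet + 0.5 * (delta * sd).sum(axis=1) + 0.5 * k * _LOG2PI
    if not np.all(np.isfinite(nll_vec)):
        raise FloatingPointError("non-finite loss during density-network training")
    n = u.shape[0]
    # d(nll)/dSigma = 0.5 (Sinv - Sinv delta delta^T Sinv), symmetric
    g = 0.5 * (sinv - sd[:, :, None] * sd[:, None, :])
    d_mu = -sd
    d_L = 2.0 * np.einsum("nij,njk->nik", g, L)
    rows, cols = np.tril_indices(k)
    d_lv = d_L[:, rows, cols]
    d_d = g[:, idx, idx] * ed
    d_out = np.concatenate([d_mu, d_lv, d_d], axis=1) / n
    gw, gb = model.mlp.backward(cache, d_out)
    return float(nll_vec.mean()), gw, gb


def train_dev_model(
    renditions: pd.DataFrame,
    architecture: str = "narrow64",
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 512,
    max_epochs: int = 300,
    patience: int = 10,
    eps: float = 1e-4,
    test_fraction: float = 0.2,
    latent_cols: list[str] | None = None,
) -> DevModel:
    """Fit the density network to one syllable's rendition table.

    The table needs ``age_dph``, ``time_of_day_h`` and latent columns
    ``z1..zk``.  The rows are internally re-split 80/20 into weight-update and
    early-stopping sets; the returned model carries the weights that achieved
    the best held-in test log likelihood.
    """
    from .synthetic import latent_columns as _lc

    cols = latent_cols if latent_cols is not None else _lc(renditions)
    if not cols:
        raise ValueError("no latent columns (z1..zk) found in rendition table")
    k = len(cols)
    x = renditions[cols].to_numpy(dtype=float)
    age = renditions["age_dph"].to_numpy(dtype=float)
    tod = renditions["time_of_day_h"].to_numpy(dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 renditions to fit a density model, got {n}")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx, fit_idx = perm[:n_test], perm[n_test:]

    age_mean = float(age[fit_idx].mean())
    age_sd = float(age[fit_idx].std())
    if age_sd == 0:
        age_sd = 1.0  # single-day corpus: z_age identically 0

    hidden = ARCHITECTURES[architecture] if isinstance(architecture, str) else list(architecture)
    n_out = k + k * (k + 1) // 2 + k
    mlp = MLP(3, list(hidden), n_out, activation="relu").init(rng)
    # head initialized at data moments: Sigma starts near diag(marginal var)
    mlp.biases[-1][:k] = x[fit_idx].mean(axis=0)
    mlp.biases[-1][k + k * (k + 1) // 2 :] = np.log(np.maximum(x[fit_idx].var(axis=0), 1e-8))
    mlp.weights[-1] *= 0.01  # small head weights keep early Sigmas well conditioned

    model = DevModel(mlp=mlp, k=k, age_mean=age_mean, age_sd=age_sd, eps=eps,
                     architecture=str(architecture))
    u_fit = encode_inputs(age[fit_idx], tod[fit_idx], age_mean, age_sd)
    x_fit = x[fit_idx]
    u_test = encode_inputs(age[test_idx], tod[test_idx], age_mean, age_sd)
    x_test = x[test_idx]

    opt = Adam(mlp, lr=lr)
    best_ll = -np.inf
    best_params = mlp.copy_params()
    best_epoch = -1
    history = []
    since_improve = 0
    n_fit = len(fit_idx)
    for epoch in range(max_epochs):
        order = rng.permutation(n_fit)
        train_nll = 0.0
        for start in range(0, n_fit, batch_size):
            b = order[start : start + batch_size]
            loss, gw, gb = _loss_and_grads(model, u_fit[b], x_fit[b])
            opt.step(gw, gb)
            train_nll += loss * b.size
        train_nll /= n_fit
        test_ll = float(np.mean(_batch_loglik(model, u_test, x_test)))
        history.append({"epoch": epoch, "train_nll": train_nll, "test_loglik": test_ll})
        if test_ll > best_ll + 1e-6:
            best_ll, best_epoch, since_improve = test_ll, epoch, 0
            best_params = mlp.copy_params()
        else:
            since_improve += 1
            if since_improve >= patience:
                break
    mlp.set_params(best_params)
    model.metadata = {
        "seed": seed, "lr": lr, "batch_size": batch_size, "max_epochs": max_epochs,
        "patience": patience, "best_epoch": best_epoch, "best_test_loglik": best_ll,
        "epochs_run": len(history), "n_renditions": n, "history": history,
        "param_count": mlp.n_params, "optimizer": "adam",
    }
    return model


def _batch_loglik(model: DevModel, u: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = model.mlp.forward(u)
    mu, L, d = model._parse(out)
    sigma = L @ np.swapaxes(L, 1, 2)
    idx = np.arange(model.k)
    sigma[:, idx, idx] += np.exp(d) + model.eps
    chol = np.linalg.cholesky(sigma)
    y = np.linalg.solve(chol, (x - mu)[:, :, None])[:, :, 0]
    return -0.5 * (y * y).sum(axis=1) - np.log(chol[:, idx, idx]).sum(axis=1) - 0.5 * model.k * _LOG2PI


# ---------------------------------------------------------------------------
# evaluation with shuffle controls
# ---------------------------------------------------------------------------

@dataclass
class LoglikReport:
    """Held-out mean log likelihood, optionally against permutation nulls."""

    mode: str
    unshuffled: float
    perm_means: np.ndarray
    n_permutations: int

    @property
    def mean_perm(self) -> float:
        return float(self.perm_means.mean()) if self.perm_means.size else np.nan

    @property
    def exceedance_fraction(self) -> float:
        """Share of permutations with mean log likelihood below the unshuffled one."""
        if not self.perm_means.size:
            return np.nan
        return float(np.mean(self.perm_means < self.unshuffled))


def eval_loglik(
    model: DevModel,
    renditions: pd.DataFrame,
    shuffle: str = "none",
    n_permutations: int = 1000,
    seed: int = 0,
    latent_cols: list[str] | None = None,
) -> LoglikReport:
    """Mean held-out log likelihood, with production-time permutation nulls.

    ``shuffle='total'`` permutes production times freely relative to latents;
    ``'within_day'`` permutes only among renditions sharing ``day_index``
    (wrong-day associations prohibited).
    """
    from .synthetic import latent_columns as _lc

    cols = latent_cols if latent_cols is not None else _lc(renditions)
    x = renditions[cols].to_numpy(dtype=float)
    age = renditions["age_dph"].to_numpy(dtype=float)
    tod = renditions["time_of_day_h"].to_numpy(dtype=float)
    mu, chol, _ = model.forward_batch(age, tod)
    idx = np.arange(model.k)
    sum_log_diag = np.log(chol[:, idx, idx]).sum(axis=1)
    const = 0.5 * model.k * _LOG2PI

    def mean_ll(perm: np.ndarray) -> float:
        y = np.linalg.solve(chol[perm], (x - mu[perm])[:, :, None])[:, :, 0]
        return float(np.mean(-0.5 * (y * y).sum(axis=1) - sum_log_diag[perm] - const))

    n = x.shape[0]
    ident = np.arange(n)
    unshuffled = mean_ll(ident)
    if shuffle == "none" or n_permutations == 0:
        return LoglikReport(shuffle, unshuffled, np.empty(0), 0)
    rng = np.random.default_rng(seed)
    if shuffle == "total":
        perms = (rng.permutation(n) for _ in range(n_permutations))
    elif shuffle == "within_day":
        day = renditions["day_index"].to_numpy()
        groups = [np.flatnonzero(day == d) for d in np.unique(day)]
        def _wd():
            p = ident.copy()
            for g in groups:
                p[g] = g[rng.permutation(g.size)]
            return p
        perms = (_wd() for _ in range(n_permutations))
    else:
        raise ValueError(f"unknown shuffle mode {shuffle!r}")
    perm_means = np.array([mean_ll(p) for p in perms])
    return LoglikReport(shuffle, unshuffled, perm_means, n_permutations)


def save_model(model: DevModel, path: str) -> None:
    """Serialize to <path>.npz (weights) + <path>.json (metadata)."""
    import json

    arrays = {}
    for i, (w, b) in enumerate(zip(model.mlp.weights, model.mlp.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path + ".npz", **arrays)
    meta = {
        "format_version": 1, "k": model.k, "age_mean": model.age_mean,
        "age_sd": model.age_sd, "eps": model.eps,
        "architecture": model.architecture, "n_in": model.mlp.n_in,
        "hidden": list(model.mlp.hidden), "n_out": model.mlp.n_out,
        "activation": model.mlp.activation,
        "metadata": {k: v for k, v in model.metadata.items() if k != "history"},
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path: str) -> DevModel:
    """Inverse of :func:`save_model`."""
    import json

    with open(path + ".json") as fh:
        meta = json.load(fh)
    data = np.load(path + ".npz")
    mlp = MLP(meta["n_in"], list(meta["hidden"]), meta["n_out"],
              activation=meta["activation"])
    i = 0
    while f"w{i}" in data:
        mlp.weights.append(data[f"w{i}"])
        mlp.biases.append(data[f"b{i}"])
        i += 1
    return DevModel(
        mlp=mlp, k=meta["k"], age_mean=meta["age_mean"], age_sd=meta["age_sd"],
        eps=meta["eps"], architecture=meta["architecture"], metadata=meta["metadata"],
    )
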