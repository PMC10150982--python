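"""Entropy trajectories, circadian entropy regression, and counterfactual
fixed-entropy simulations of development.

The differential entropy of a fitted k-dimensional Gaussian,

    H = 1/2 ln|Sigma| + k/2 (1 + ln 2 pi)    [nats],

summarizes the overall magnitude of rendition-to-rendition variation at one
production time.  Model entropy is sampled on a 5-minute query grid inside
the lights-on window, keeping only query times whose centered 30-minute
window (closed bounds) contains at least 30 training renditions.

The fixed-entropy counterfactual clamps each covariance's determinant to a
per-day target (the day's minimum over the retained query grid) by dividing
every eigenvalue by ratio**(1/k): the eigenbasis and eigenvalue ratios — the
*allocation* of variation — are untouched, only the overall magnitude moves.
Sampling one draw per held-out observation time from baseline or clamped
models yields the simulated developmental datasets used by the overnight
shift analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lmm import LmmResult, fit_mixed

__all__ = [
    "gaussian_entropy",
    "sample_query_times",
    "entropy_trajectory",
    "fit_entropy_lmm",
    "daily_min_det",
    "daily_targets",
    "fix_entropy",
    "simulate_development",
]

log = logging.getLogger(__name__)
_ENTROPY_CONST = 0.5 * (1.0 + np.log(2.0 * np.pi))  # nats per dimension


def gaussian_entropy(sigma: np.ndarray, k: int | None = None) -> float:
    """Differential entropy (nats) of N(mu, sigma): 1/2 ln|Sigma| + k/2 (1+ln 2pi)."""
    sigma = np.asarray(sigma, dtype=float)
    if k is None:
        k = sigma.shape[0]
    if sigma.shape != (k, k):
        raise ValueError(f"covariance shape {sigma.shape} does not match k={k}")
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is not symmetric positive definite") from exc
    return float(np.log(np.diag(chol)).sum() + k * _ENTROPY_CONST)


def sample_query_times(
    renditions: pd.DataFrame,
    day_window: tuple[float, float],
    interval_h: float = 5.0 / 60.0,
    window_h: float = 0.5,
    min_count: int = 30,
) -> pd.DataFrame:
    """Query-time grid with enough local training support.

    For every day present in ``renditions`` (one syllable's table), lays a
    grid at ``interval_h`` steps across the lights-on window and keeps the
    query times whose centered ``window_h`` window (closed on both ends)
    contains at least ``min_count`` renditions that day.  Returns columns
    ``age_dph, time_of_day_h, day_index, n_support``.
    """
    if len(renditions) == 0:
        return pd.DataFrame(columns=["age_dph", "time_of_day_h", "day_index", "n_support"])
    on, off = day_window
    grid = on + interval_h * np.arange(int(np.floor((off - on) / interval_h)) + 1)
    half = window_h / 2.0
    out = []
    for day, sub in renditions.groupby("day_index"):
        tods = np.sort(sub["time_of_day_h"].to_numpy(dtype=float))
        lo = np.searchsorted(tods, grid - half, side="left")
        hi = np.searchsorted(tods, grid + half, side="right")
        n = hi - lo
        keep = n >= min_count
        if keep.any():
            out.append(pd.DataFrame({
                "age_dph": day + grid[keep] / 24.0,
                "time_of_day_h": grid[keep],
                "day_index": int(day),
                "n_support": n[keep],
            }))
    if not out:
        return pd.DataFrame(columns=["age_dph", "time_of_day_h", "day_index", "n_support"])
    return pd.concat(out, ignore_index=True)


def _snapshots(model, ages, tods):
    """(mu (n,k), sigma (n,k,k)) for any model exposing forward_batch or snapshot."""
    if hasattr(model, "forward_batch"):
        mu, chol, _ = model.forward_batch(ages, tods)
        return mu, chol @ np.swapaxes(chol, 1, 2)
    mus, sigmas = [], []
    for a, t in zip(ages, tods):
        snap = model.snapshot(a, t)
        mus.append(snap.mu)
        sigmas.append(snap.Sigma)
    return np.array(mus), np.array(sigmas)


def entropy_trajectory(model, query_times: pd.DataFrame,
                       bird_id: str | None = None,
                       syllable_id: str | None = None) -> pd.DataFrame:
    """Model entropy at each retained query time (one row per query)."""
    q = query_times.reset_index(drop=True)
    ages = q["age_dph"].to_numpy(dtype=float)
    tods = q["time_of_day_h"].to_numpy(dtype=float)
    _, sigma = _snapshots(model, ages, tods)
    k = sigma.shape[1]
    sign, logdet = np.linalg.slogdet(sigma)
    if np.any(sign <= 0):
        raise ValueError("model produced a non-positive-definite covariance")
    out = q.copy()
    out["entropy"] = 0.5 * logdet + k * _ENTROPY_CONST
    out["k"] = k
    if bird_id is not None:
        out["bird_id"] = bird_id
    if syllable_id is not None:
        out["syllable_id"] = syllable_id
    return out


def fit_entropy_lmm(samples: pd.DataFrame, variant: str = "tod_only",
                    reml: bool = True) -> LmmResult:
    """Hierarchical regression of entropy on time of day (and optionally age).

    ``tod_only``:  entropy ~ 1 + timeOfDay, random intercept+slope by bird
    and by syllable.  ``tod_by_age`` adds main effect of age and the
    age-by-time-of-day interaction, with random effects for all coefficients.
    """
    if variant == "tod_only":
        fixed = ["time_of_day_h"]
    elif variant == "tod_by_age":
        fixed = ["time_of_day_h", "age_dph", "time_of_day_h:age_dph"]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return fit_mixed(samples, "entropy", fixed, reml=reml)


def daily_min_det(model, day_query_times: pd.DataFrame) -> float:
    """Target determinant for one day: min |Sigma| over that day's query grid."""
    if len(day_query_times) == 0:
        raise ValueError("no valid query times for this day")
    _, sigma = _snapshots(
        model,
        day_query_times["age_dph"].to_numpy(dtype=float),
        day_query_times["time_of_day_h"].to_numpy(dtype=float),
    )
    sign, logdet = np.linalg.slogdet(sigma)
    if np.any(sign <= 0):
        raise ValueError("model produced a non-positive-definite covariance")
    return float(np.exp(logdet.min()))


def daily_targets(model, query_times: pd.DataFrame) -> dict[int, float]:
    """Per-day minimum-determinant targets over the retained query grid."""
    return {
        int(day): daily_min_det(model, sub)
        for day, sub in query_times.groupby("day_index")
    }


def fix_entropy(sigma: np.ndarray, target_det: float) -> np.ndarray:
    """Rescale eigenvalues isotropically so det(Sigma) equals ``target_det``.

    Sigma = Q Lambda Q^T; every eigenvalue is divided by
    (det(Sigma)/target_det)**(1/k), preserving the eigenbasis and all
    eigenvalue ratios (the allocation factor) exactly.
    """
    sigma = np.asarray(sigma, dtype=float)
    if target_det <= 0:
        raise ValueError(f"target determinant must be positive, got {target_det}")
    lam, q = np.linalg.eigh(sigma)
    if lam.min() <= 0:
        raise ValueError("covariance is not symmetric positive definite")
    k = sigma.shape[0]
    log_ratio = np.log(lam).sum() - np.log(target_det)
    lam_scaled = lam * np.exp(-log_ratio / k)
    return (q * lam_scaled) @ q.T


def simulate_development(
    model,
    observations: pd.DataFrame,
    mode: str = "baseline",
    seed: int = 0,
    targets: dict[int, float] | None = None,
    query_times: pd.DataFrame | None = None,
    latent_prefix: str = "z",
) -> pd.DataFrame:
    """One model draw per held-out observation time.

    ``mode='baseline'`` samples the model's Gaussian at each observation's
    production time; ``mode='fixed_entropy'`` first clamps each covariance's
    determinant to its day's target (``targets``, or computed from
    ``query_times`` via :func:`daily_targets`).  Observation timestamps are
    carried over; latent columns are replaced by the draws.  Deterministic
    given ``seed`` (per-observation substreams).  Days without a target are
    skipped with a log message.
    """
    if mode not in ("baseline", "fixed_entropy"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    obs = observations.reset_index(drop=True)
    if mode == "fixed_entropy":
        if targets is None:
            if query_times is None:
                raise ValueError("fixed_entropy mode needs `targets` or `query_times`")
            targets = daily_targets(model, query_times)
        have = obs["day_index"].isin(list(targets))
        if not have.all():
            skipped = sorted(obs.loc[~have, "day_index"].unique())
            log.warning("skipping %d observations on days without an entropy target: %s",
                        int((~have).sum()), skipped)
            obs = obs[have].reset_index(drop=True)
    ages = obs["age_dph"].to_numpy(dtype=float)
    tods = obs["time_of_day_h"].to_numpy(dtype=float)
    mu, sigma = _snapshots(model, ages, tods)
    k = sigma.shape[1]
    if mode == "fixed_entropy":
        lam, q = np.linalg.eigh(sigma)
        logdet = np.log(lam).sum(axis=1)
        tvec = np.array([targets[int(d)] for d in obs["day_index"]])
        lam = lam * np.exp(-(logdet - np.log(tvec))[:, None] / k)
        sigma = np.einsum("nij,nj,nkj->nik", q, lam, q)
    chol = np.linalg.cholesky(sigma)
    draws = np.empty((len(obs), k))
    for i in range(len(obs)):
        eps = np.random.default_rng([seed, i]).standard_normal(k)
        draws[i] = mu[i] + chol[i] @ eps
    out = obs.copy()
    for j in range(k):
        out[f"{latent_prefix}{j + 1}"] = draws[:, j]
    out["condition"] = mode
    return out
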