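"""Time-binned quantiles of predicted age and overnight shift analysis.

Renditions carrying predicted ages are binned by production time in 0.1-day
bins anchored at integer days post hatch; bins with fewer than 30 renditions
are discarded.  Within every retained bin, empirical quantiles of predicted
age are taken at a configurable set of percentile levels (default 1, 5, 25,
50, 75, 95, 99; linear interpolation between order statistics).  The
overnight shift at level i between consecutive days j and j+1 is

    shift_i = Q_i(first bin of day j+1) - Q_i(last bin of day j),

discarded when the two bins' centers are more than 0.6 days apart.  The
hierarchical regression of shifts on percentile level (scaled to [0, 1]),
optionally crossed with a baseline/fixed-entropy simulation condition,
quantifies whether overnight change depends on where in the maturity
distribution one looks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lmm import LmmResult, fit_mixed

__all__ = [
    "DEFAULT_LEVELS",
    "LEVEL_SETS",
    "bin_and_quantile",
    "overnight_shifts",
    "fit_shift_lmm",
    "alternative_binnings",
]

log = logging.getLogger(__name__)

DEFAULT_LEVELS = (1, 5, 25, 50, 75, 95, 99)
LEVEL_SETS = {
    "3-level": (1, 50, 99),
    "7-level": DEFAULT_LEVELS,
    "11-level": (1, 5, 15, 25, 40, 50, 60, 75, 85, 95, 99),
}
_GROUPS = ["bird_id", "syllable_id"]


def bin_and_quantile(
    renditions: pd.DataFrame,
    pred_col: str = "predicted_age",
    bin_width: float = 0.1,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    min_n: int = 30,
) -> pd.DataFrame:
    """Per-bin empirical percentiles of predicted age (long format).

    Bins are ``bin_width``-day intervals of ``age_dph`` anchored at integer
    days.  Groups carrying a ``condition`` column are binned separately per
    condition.  Returns one row per (bin, level) with columns
    ``bird_id, syllable_id, [condition,] day_index, bin_start, bin_center,
    n, level, value``; under-filled bins are dropped.
    """
    if not levels:
        raise ValueError("empty percentile level set")
    df = renditions
    keys = [*_GROUPS] + (["condition"] if "condition" in df.columns else [])
    bin_idx = np.floor(df["age_dph"].to_numpy(dtype=float) / bin_width + 1e-9).astype(np.int64)
    df = df.assign(_bin=bin_idx)
    lv = np.asarray(levels, dtype=float)
    rows = []
    for key, sub in df.groupby([*keys, "_bin"], sort=True):
        n = len(sub)
        if n < min_n:
            continue
        b = key[-1]
        qs = np.quantile(sub[pred_col].to_numpy(dtype=float), lv / 100.0)  # linear (type-7)
        start = b * bin_width
        base = dict(zip(keys, key[:-1]))
        base.update(day_index=int(np.floor(start)), bin_start=start,
                    bin_center=start + bin_width / 2.0, n=n)
        for level, value in zip(levels, qs):
            rows.append({**base, "level": level, "value": value})
    cols = [*keys, "day_index", "bin_start", "bin_center", "n", "level", "value"]
    return pd.DataFrame(rows, columns=cols)


def overnight_shifts(bins: pd.DataFrame, max_gap: float = 0.6) -> pd.DataFrame:
    """Percentile-wise overnight changes between consecutive days.

    For each syllable (and condition, when present) and each consecutive day
    pair (j, j+1) with a retained terminal bin on day j and initial bin on
    day j+1 whose centers are at most ``max_gap`` days apart, emits one
    record per percentile level: ``shift = first(j+1) - last(j)``.
    """
    if len(bins) == 0:
        return pd.DataFrame(columns=[*_GROUPS, "day_j", "level", "percentile01", "shift", "gap"])
    keys = [*_GROUPS] + (["condition"] if "condition" in bins.columns else [])
    records = []
    for key, sub in bins.groupby(keys, sort=True):
        days = np.sort(sub["day_index"].unique())
        for day in days:
            if day + 1 not in days:
                continue
            last_bin = sub[sub["day_index"] == day].nlargest(1, "bin_center", keep="all")
            first_bin = sub[sub["day_index"] == day + 1].nsmallest(1, "bin_center", keep="all")
            gap = float(first_bin["bin_center"].iloc[0] - last_bin["bin_center"].iloc[0])
            if gap > max_gap:
                log.info("skipping overnight pair %s day %d: gap %.2f d > %.2f d", key, day, gap, max_gap)
                continue
            evening = last_bin.set_index("level")["value"]
            morning = first_bin.set_index("level")["value"]
            base = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
            for level in evening.index.intersection(morning.index):
                records.append({
                    **base, "day_j": int(day), "level": level,
                    "percentile01": level / 100.0,
                    "shift": float(morning[level] - evening[level]), "gap": gap,
                })
    cols = [*keys, "day_j", "level", "percentile01", "shift", "gap"]
    return pd.DataFrame(records, columns=cols)


def fit_shift_lmm(records: pd.DataFrame, with_condition: bool = False,
                  reml: bool = True) -> LmmResult:
    """Hierarchical regression of overnight shifts on percentile level.

    Fixed effects: intercept + percentile (on [0, 1]); with
    ``with_condition`` also a fixed-entropy indicator (``cond`` = 1 for the
    fixed-entropy simulation) and its interaction with percentile.  Random
    effects for the fitted coefficients at the bird and syllable levels.
    """
    df = records.copy()
    if with_condition:
        if "condition" not in df.columns or df["condition"].nunique() < 2:
            raise ValueError("with_condition requires records from both simulation conditions")
        df["cond"] = (df["condition"] == "fixed_entropy").astype(float)
        fixed = ["percentile01", "cond", "percentile01:cond"]
        slopes = ["percentile01", "cond"]
    else:
        fixed = ["percentile01"]
        slopes = ["percentile01"]
    return fit_mixed(df, "shift", fixed, slope_terms=slopes, reml=reml)


def alternative_binnings(
    renditions: pd.DataFrame,
    level_sets: dict[str, tuple[float, ...]] | None = None,
    pred_col: str = "predicted_age",
    bin_width: float = 0.1,
    min_n: int = 30,
    max_gap: float = 0.6,
    with_condition: bool = False,
) -> dict[str, tuple[pd.DataFrame, LmmResult]]:
    """Robustness sweep over percentile binning choices.

    Runs the bin/shift/regression pipeline once per named level set (default
    the 3-, 7- and 11-level sets) and returns ``{name: (shift records,
    LmmResult)}`` so the sign pattern of the fixed effects can be compared
    across binnings.
    """
    sets = LEVEL_SETS if level_sets is None else level_sets
    out = {}
    for name, levels in sets.items():
        if not levels:
            raise ValueError(f"level set {name!r} is empty")
        bins = bin_and_quantile(renditions, pred_col=pred_col, bin_width=bin_width,
                                levels=tuple(levels), min_n=min_n)
        recs = overnight_shifts(bins, max_gap=max_gap)
        out[name] = (recs, fit_shift_lmm(recs, with_condition=with_condition))
    return out
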