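"""Linear mixed-effects fitting shared by the entropy and shift analyses.

Both analyses use the same hierarchical design: fixed effects of interest
plus correlated random intercept/slope pairs at the bird level and at the
syllable level (syllables are nested within birds).  Fitting goes through
statsmodels MixedLM with the bird as the grouping factor, a ``re_formula``
for the bird-level effects, and variance components for the syllable-level
effects.  Variance components in statsmodels are mutually independent, so
syllable-level intercepts and slopes are uncorrelated here — a mild
restriction relative to a fully correlated syllable-level covariance.

Degenerate inputs (noise-free responses, a single grouping level, boundary
fits) are handled by tiered fallback: full structure, then bird-level
random effects only, then ordinary least squares.  For an exactly linear
response y = Xb any generalized-least-squares weighting returns b, so the
OLS fallback is the correct limit; the result is flagged, never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["LmmResult", "fit_mixed"]


@dataclass
class LmmResult:
    """Fixed-effect estimates and diagnostics from one hierarchical fit."""

    formula: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    random_effect_sd: dict[str, float]
    n_obs: int
    converged: bool
    singular: bool
    method: str
    notes: list[str] = field(default_factory=list)
    cov_params: pd.DataFrame | None = None
    df_t: float | None = None  # between-groups t df; None means normal reference

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def significant(self, name: str, alpha: float = 0.05) -> bool:
        return self.pvalues[name] < alpha

    def predict_fixed(self, design: dict[str, np.ndarray]) -> np.ndarray:
        """Marginal (fixed-effects-only) prediction on named covariates."""
        names = list(self.params)
        cols = []
        for nm in names:
            if nm == "Intercept":
                cols.append(np.ones_like(next(iter(design.values()), np.array([1.0])), dtype=float))
            else:
                cols.append(_eval_term(nm, design))
        x = np.column_stack(cols)
        return x @ np.array([self.params[nm] for nm in names])

    def wald_linear_combo(self, weights: dict[str, float]) -> tuple[float, float, float]:
        """(estimate, SE, two-sided p) for a linear combination of fixed effects."""
        from scipy.stats import norm, t as t_dist

        names = list(self.params)
        w = np.array([weights.get(nm, 0.0) for nm in names])
        est = float(w @ np.array([self.params[nm] for nm in names]))
        if self.cov_params is None:
            raise ValueError("fit did not retain a fixed-effect covariance matrix")
        cov = self.cov_params.loc[names, names].to_numpy()
        se = float(np.sqrt(w @ cov @ w))
        if se <= 0:
            return est, se, np.nan
        z = abs(est) / se
        p = 2.0 * (t_dist.sf(z, self.df_t) if self.df_t else norm.sf(z))
        return est, se, float(p)


def _eval_term(term: str, design: dict[str, np.ndarray]) -> np.ndarray:
    out = None
    for factor in term.split(":"):
        v = np.asarray(design[factor], dtype=float)
        out = v if out is None else out * v
    return out


def _extract(result, fe_names, formula, method, notes, singular, df_t: float | None = None) -> LmmResult:
    from scipy.stats import t as t_dist

    params = {nm: float(result.params[nm]) for nm in fe_names}
    bse = {nm: float(result.bse[nm]) for nm in fe_names}
    if df_t is not None and df_t >= 1:
        # small-sample inference: t reference with between-groups df instead
        # of the Wald normal, which undercovers with a handful of birds
        tcrit = float(t_dist.ppf(0.975, df_t))
        pvals = {nm: float(2.0 * t_dist.sf(abs(params[nm] / bse[nm]), df_t)) if bse[nm] > 0 else np.nan
                 for nm in fe_names}
        conf = {nm: (params[nm] - tcrit * bse[nm], params[nm] + tcrit * bse[nm]) for nm in fe_names}
    else:
        pvals = {nm: float(result.pvalues[nm]) for nm in fe_names}
        ci = result.conf_int()
        conf = {nm: (float(ci.loc[nm, 0]), float(ci.loc[nm, 1])) for nm in fe_names}
    re_sd: dict[str, float] = {}
    if method == "mixedlm" and getattr(result, "cov_re", None) is not None:
        cov_re = np.asarray(result.cov_re)
        re_names = getattr(result.model.data, "exog_re_names", None) or []
        for i, nm in enumerate(re_names):
            if i < cov_re.shape[0]:
                re_sd[f"group:{nm}"] = float(np.sqrt(max(cov_re[i, i], 0.0)))
        vc_names = result.model.exog_vc.names if getattr(result.model, "exog_vc", None) else []
        for nm, v in zip(vc_names, np.atleast_1d(getattr(result, "vcomp", []))):
            re_sd[f"vc:{nm}"] = float(np.sqrt(max(v, 0.0)))
    converged = bool(getattr(result, "converged", True)) and all(np.isfinite(list(bse.values())))
    cov_fe = result.cov_params()
    if isinstance(cov_fe, pd.DataFrame):
        cov_fe = cov_fe.loc[fe_names, fe_names]
    return LmmResult(
        formula=formula, params=params, bse=bse, pvalues=pvals, conf_int=conf,
        random_effect_sd=re_sd, n_obs=int(result.nobs), converged=converged,
        singular=singular, method=method, notes=notes, cov_params=cov_fe, df_t=df_t,
    )


def fit_mixed(
    df: pd.DataFrame,
    response: str,
    fixed: list[str],
    slope_terms: list[str] | None = None,
    bird_col: str = "bird_id",
    syl_col: str = "syllable_id",
    reml: bool = True,
) -> LmmResult:
    """Fit ``response ~ 1 + fixed`` with random intercepts and the given
    random-slope terms at the bird and syllable levels.

    ``fixed`` are patsy-style terms (e.g. ``"time_of_day_h"`` or
    ``"percentile01:cond"``); ``slope_terms`` defaults to all non-interaction
    fixed terms.  Returns an :class:`LmmResult`; ``converged``/``singular``
    flags and ``notes`` report any fallback taken.
    """
    data = df.reset_index(drop=True).copy()
    formula = f"{response} ~ 1 + " + " + ".join(fixed) if fixed else f"{response} ~ 1"
    if slope_terms is None:
        slope_terms = [t for t in fixed if ":" not in t]
    notes: list[str] = []

    n_birds = data[bird_col].nunique()
    n_syls = data.groupby(bird_col)[syl_col].nunique().sum()

    attempts = []
    if n_birds >= 2 and n_syls > n_birds:
        attempts.append("full")
    if n_birds >= 2:
        attempts.append("bird_only")
    elif data[syl_col].nunique() >= 2:
        attempts.append("syl_as_group")
    attempts.append("ols")

    re_formula = "~ 1" + "".join(f" + {t}" for t in slope_terms)
    vc = {"int": f"0 + C({syl_col})"}
    for i, t in enumerate(slope_terms):
        vc[f"slope{i}"] = f"0 + C({syl_col}):{t}"

    for tier in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if tier == "ols":
                    res = smf.ols(formula, data=data).fit()
                    fe = list(res.params.index)
                    notes.append("fallback: ordinary least squares (degenerate or unstable mixed fit)")
                    return _extract(res, fe, formula, "ols", notes, singular=True)
                group_col = syl_col if tier == "syl_as_group" else bird_col
                df_t = max(float(data[group_col].nunique() - 1), 1.0)
                if tier == "full":
                    model = smf.mixedlm(formula, data=data, groups=data[bird_col],
                                        re_formula=re_formula, vc_formula=vc)
                elif tier == "bird_only":
                    model = smf.mixedlm(formula, data=data, groups=data[bird_col],
                                        re_formula=re_formula)
                    if "full" in attempts:
                        notes.append("fallback: bird-level random effects only")
                else:  # syl_as_group
                    model = smf.mixedlm(formula, data=data, groups=data[syl_col],
                                        re_formula=re_formula)
                    notes.append("fallback: single bird; syllable used as grouping factor")
                res = model.fit(reml=reml, method="lbfgs", maxiter=200, disp=False)
            fe = list(model.exog_names)
            if not np.all(np.isfinite([res.params[nm] for nm in fe])):
                raise np.linalg.LinAlgError("non-finite fixed effects")
            bse_ok = np.all(np.isfinite([res.bse[nm] for nm in fe]))
            cov_re = np.asarray(res.cov_re) if res.cov_re is not None else np.empty((0, 0))
            vcomp = np.atleast_1d(getattr(res, "vcomp", np.empty(0)))
            boundary = (cov_re.size and np.any(np.diag(cov_re) < 1e-10)) or (
                vcomp.size and np.any(vcomp < 1e-10))
            if not bse_ok:
                raise np.linalg.LinAlgError("non-finite standard errors")
            if boundary:
                notes.append("variance component at boundary (singular fit)")
            return _extract(res, fe, formula, "mixedlm", notes, singular=bool(boundary), df_t=df_t)
        except (np.linalg.LinAlgError, ValueError, KeyError) as exc:
            notes.append(f"{tier} structure failed: {type(exc).__name__}")
            continue
    raise RuntimeError("all fitting tiers failed")  # pragma: no cover
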