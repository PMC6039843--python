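"""Cognitive index construction, baseline group tables and slope estimation.

Domain indices (executive function, processing speed, working memory,
long-term memory, plus a global score) are arithmetic means of the available
component z-scores.  Annualised cognitive change is estimated with a
two-level linear mixed-effects model (random intercept and slope per
subject, unstructured covariance, maximum likelihood); the per-subject BLUP
slopes are shrunken toward the population mean, so they are always at most
as dispersed as per-subject OLS slopes, which are also emitted as a
fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("svdstrat")


@dataclass
class SlopeEstimate:
    """Per-subject annualised slopes (z/year) for one cognitive domain."""

    subject_ids: list[str]
    lme_slopes: np.ndarray  # BLUP: fixed slope + random slope effect
    ols_slopes: np.ndarray
    method: str  # "LME-random-slope" or "per-subject-OLS" (fallback)
    fixed_slope: float


def domain_index(component_scores) -> float:
    """Mean of the available (non-NaN) component z-scores."""
    x = np.asarray(component_scores, dtype=float)
    present = np.isfinite(x)
    if not present.any():
        raise ValueError("all component scores missing")
    n_missing = int(np.sum(~present))
    if n_missing:
        logger.info("domain index computed with %d missing component(s)", n_missing)
    return float(x[present].mean())


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(np.sum(tc * (y - y.mean())) / np.sum(tc * tc))


def fit_random_slopes(scores, times, subjects) -> SlopeEstimate:
    """Per-subject annualised slopes from a random-intercept/random-slope LME.

    ``scores``, ``times`` and ``subjects`` are long-format aligned vectors
    (one row per visit).  The model is fitted by maximum likelihood with an
    unstructured 2x2 random-effect covariance; on non-convergence (or
    degenerate zero-variance data) per-subject OLS slopes are used instead.
    """
    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "time": np.asarray(times, dtype=float),
        "subject": np.asarray(subjects),
    })
    counts = df.groupby("subject")["time"].nunique()
    if (counts >= 2).mean() < 0.5:
        raise ValueError("need >= 2 visits for at least half the subjects")
    ids = list(counts.index)
    ols = np.array([
        _ols_slope(g["time"].to_numpy(), g["score"].to_numpy())
        if g["time"].nunique() >= 2 else np.nan
        for _, g in df.groupby("subject")
    ])

    import statsmodels.formula.api as smf
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("score ~ time", df, groups=df["subject"],
                                re_formula="~time")
            fit = model.fit(reml=False, method="lbfgs")
        if not fit.converged:
            raise RuntimeError("LME did not converge")
        fixed = float(fit.fe_params["time"])
        re = fit.random_effects
        lme = np.array([fixed + float(re[s].get("time", 0.0)) for s in ids])
        method = "LME-random-slope"
    except Exception as exc:  # non-convergence / singular fit
        logger.warning("LME fit failed (%s); using per-subject OLS slopes", exc)
        lme = ols.copy()
        fixed = float(np.nanmean(ols))
        method = "per-subject-OLS"
    return SlopeEstimate(ids, lme, ols, method, fixed)


#: variables treated as ordinal/bounded, tested with Kruskal-Wallis
DEFAULT_NONPARAMETRIC = ("mmse", "rankin")


def baseline_comparison(df: pd.DataFrame, group_col: str = "group",
                        variables: list[str] | None = None,
                        nonparametric: tuple[str, ...] = DEFAULT_NONPARAMETRIC,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Two-group baseline comparison with Bonferroni-corrected significance.

    Continuous variables get a two-sample t-test; variables named in
    ``nonparametric`` get a Kruskal-Wallis test.  The corrected threshold is
    ``alpha / n_variables`` (17 variables reproduce the conventional
    P < 0.003 family level).
    """
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if variables is None:
        variables = [c for c in df.columns
                     if c != group_col and pd.api.types.is_numeric_dtype(df[c])]
    corrected = alpha / len(variables)
    a = df[df[group_col] == groups[0]]
    b = df[df[group_col] == groups[1]]
    rows = []
    for var in variables:
        xa, xb = a[var].dropna(), b[var].dropna()
        if xa.nunique() <= 1 and xb.nunique() <= 1 and set(xa) == set(xb):
            rows.append({"variable": var, "test": "skipped (constant)",
                         "statistic": np.nan, "p": np.nan, "significant": False})
            continue
        if var in nonparametric:
            stat, p = stats.kruskal(xa, xb)
            test = "kruskal-wallis"
        else:
            stat, p = stats.ttest_ind(xa, xb)
            test = "t-test"
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "p": float(p), "significant": bool(p < corrected)})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = corrected
    return out
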