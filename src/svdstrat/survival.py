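"""Time-to-dementia analysis: SVDp threshold selection, Kaplan-Meier curves,
log-rank tests and SVM x vascular-burden stratification.

The vascular-burden marker is SVDp (WMH as a percentage of total cerebral
volume).  A discrimination threshold is selected by maximising Youden's J
(sensitivity + specificity - 1) over a grid; survival in the four strata
(SVM prediction +/- crossed with burden high/low) is summarised by the
product-limit estimator and compared with the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io_core import FOLLOW_UP_YEARS


@dataclass
class SurvivalCurve:
    """Product-limit estimate with risk-set bookkeeping."""

    times: np.ndarray  # distinct observed times (events and censorings)
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray
    events: np.ndarray
    median: float  # years; NaN when S never reaches 0.5
    n: int

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ThresholdReport:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_j: np.ndarray
    selected: float
    selected_j: float


def threshold_select(marker, outcome, grid=None) -> ThresholdReport:
    """Sensitivity/specificity over a threshold grid; Youden-optimal pick.

    A subject is called positive when marker >= threshold.  Ties in J are
    broken toward the smallest threshold.
    """
    x = np.asarray(marker, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) marker")
    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)
    pos = x[y]
    neg = x[~y]
    sens = np.array([(pos >= t).mean() for t in grid])
    spec = np.array([(neg < t).mean() for t in grid])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximiser
    return ThresholdReport(grid, sens, spec, j, float(grid[best]), float(j[best]))


def kaplan_meier(event_times, event_flags) -> SurvivalCurve:
    """Product-limit survival estimate; censored subjects leave the risk set
    at their time without stepping the curve."""
    t = np.asarray(event_times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if np.any(t < 0):
        raise ValueError("negative event/censoring times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    keep = np.ones(len(times), dtype=bool)
    if len(times) and times[0] == 0.0 and 0.0 not in t:
        keep[0] = False  # synthetic t=0 row added by the fitter
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return SurvivalCurve(
        times[keep], surv[keep],
        table["at_risk"].to_numpy()[keep], table["observed"].to_numpy()[keep],
        median, len(t))


def logrank_test(event_times, event_flags, group_labels) -> tuple[float, float]:
    """Log-rank chi-square and p-value across >= 2 groups."""
    t = np.asarray(event_times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    g = np.asarray(group_labels)
    if len(set(g.tolist())) < 2:
        raise ValueError("need at least 2 groups")
    if not e.any():
        raise ValueError("need at least 1 event")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def stratified_analysis(prediction_positive, svdp_values, threshold,
                        event_times, event_flags,
                        horizon: float = FOLLOW_UP_YEARS) -> dict:
    """Four-stratum survival: SVM prediction crossed with vascular burden.

    Returns per-stratum Kaplan-Meier curves and 5-year conversion
    probabilities (1 - S(horizon)), plus the log-rank test between the SVM
    prediction groups.  Empty strata are reported as missing.
    """
    pred = np.asarray(prediction_positive, dtype=bool)
    svdp = np.asarray(svdp_values, dtype=float)
    t = np.asarray(event_times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if not svdp.min() <= threshold <= svdp.max():
        raise ValueError("threshold outside the marker range")
    high = svdp >= threshold
    strata = {
        "positive/high-burden": pred & high,
        "positive/low-burden": pred & ~high,
        "negative/high-burden": ~pred & high,
        "negative/low-burden": ~pred & ~high,
    }
    curves: dict[str, SurvivalCurve | None] = {}
    conversion: dict[str, float] = {}
    for name, sel in strata.items():
        if not sel.any():
            warnings.warn(f"empty stratum {name!r}")
            curves[name] = None
            conversion[name] = float("nan")
            continue
        curve = kaplan_meier(t[sel], e[sel])
        curves[name] = curve
        conversion[name] = 1.0 - curve.at(horizon)
    chi2, p = logrank_test(t, e, np.where(pred, "positive", "negative"))
    return {
        "curves": curves,
        "conversion_5y": conversion,
        "logrank_chi2": chi2,
        "logrank_p": p,
        "table": pd.DataFrame({
            "stratum": list(conversion),
            "n": [int(s.sum()) for s in strata.values()],
            "conversion_5y": list(conversion.values()),
        }),
    }
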