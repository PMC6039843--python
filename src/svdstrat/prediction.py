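"""Baseline-MRI dementia prediction with a linear SVM.

Protocol: leave-one-out cross-validation; within each training fold the
confounds (age, sex, TIV, premorbid IQ) are regressed out of every feature
using training rows only, features are mean-centred with training means, and
a soft-margin linear SVM (C = 1, the toolbox default) is trained; the
held-out subject's decision value and sign are recorded.  Metrics are
assembled from held-out predictions only, and significance is assessed by
permuting labels and re-running the complete pipeline.  Balanced accuracy —
the mean of sensitivity and specificity — is the headline metric because of
the heavy class imbalance (roughly one convertor per four non-convertors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FeatureMatrix, extract_features  # re-exported
from .io_core import Volume

__all__ = [
    "FeatureMatrix", "extract_features", "PredictionResult",
    "classification_metrics", "loo_predict", "permutation_pvalue",
    "roi_prediction_table",
]


@dataclass
class PredictionResult:
    """Held-out decisions, confusion counts and the full metric suite."""

    decision_values: np.ndarray
    predicted: np.ndarray  # boolean, positive = predicted convertor
    labels: np.ndarray  # boolean ground truth
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)


def _rank_auc(decision_values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC with half credit for ties (Mann-Whitney form)."""
    pos = decision_values[labels]
    neg = decision_values[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _ratio(num: float, den: float) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def classification_metrics(tp: int, fp: int, tn: int, fn: int,
                           decision_values=None, labels=None) -> dict[str, float]:
    """Metric suite from confusion counts (percentages) plus rank AUC.

    Undefined ratios (zero denominators) are reported as NaN, never as 0.
    """
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("negative confusion count")
    n = tp + fp + tn + fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    metrics = {
        "total_accuracy": _ratio(tp + tn, n),
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "auc": float("nan"),
    }
    if decision_values is not None and labels is not None:
        metrics["auc"] = _rank_auc(np.asarray(decision_values),
                                   np.asarray(labels, dtype=bool))
    return metrics


def _confound_design(confounds, n: int) -> np.ndarray:
    if confounds is None:
        return np.ones((n, 1))
    cov = np.asarray(confounds, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError("confound rows must align with feature rows")
    return np.column_stack([cov, np.ones(n)])


def _fit_fold(F: np.ndarray, Cmat: np.ndarray, y: np.ndarray,
              train: np.ndarray, C: float):
    """Train one fold's model using *training rows only*.

    Confound regression coefficients and the feature means are estimated on
    the training rows and then applied to any row via the returned
    ``transform`` — the held-out subject never influences the fold's model.
    """
    if y[train].all() or not y[train].any():
        raise ValueError("a class is absent from a training fold")
    beta, *_ = np.linalg.lstsq(Cmat[train], F[train], rcond=None)
    centre = (F[train] - Cmat[train] @ beta).mean(axis=0)

    def transform(rows: np.ndarray, conf_rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(rows)
        conf_rows = np.atleast_2d(conf_rows)
        return rows - conf_rows @ beta - centre

    clf = SVC(kernel="linear", C=C)
    clf.fit(transform(F[train], Cmat[train]), y[train].astype(int))
    return clf, transform


def loo_predict(features, labels, confounds=None, C: float = 1.0) -> PredictionResult:
    """Leave-one-out linear-SVM prediction with fold-wise confound removal.

    ``features`` may be a :class:`FeatureMatrix` or a plain (n, p) array;
    ``labels`` is boolean (True = convertor).
    """
    F = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, dtype=bool)
    n = F.shape[0]
    if y.shape != (n,):
        raise ValueError("labels must align with feature rows")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    Cmat = _confound_design(confounds, n)

    decision = np.empty(n)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        clf, transform = _fit_fold(F, Cmat, y, train, C)
        decision[i] = clf.decision_function(transform(F[i], Cmat[i]))[0]
    if not np.all(np.isfinite(decision)):
        raise ValueError("non-finite decision value(s)")

    predicted = decision > 0.0
    tp = int(np.sum(predicted & y))
    fp = int(np.sum(predicted & ~y))
    tn = int(np.sum(~predicted & ~y))
    fn = int(np.sum(~predicted & y))
    metrics = classification_metrics(tp, fp, tn, fn, decision, y)
    return PredictionResult(decision, predicted, y, tp, fp, tn, fn, metrics)


def permutation_pvalue(features, labels, confounds=None,
                       statistic: str | Callable[[PredictionResult], float] = "balanced_accuracy",
                       n_permutations: int = 99, seed: int = 0,
                       C: float = 1.0) -> float:
    """Permutation p-value for a LOO prediction statistic.

    Labels are permuted and the complete leave-one-out pipeline (confound
    removal, centring, SVM) re-run per permutation;
    p = (1 + #{permuted statistic >= observed}) / (1 + B).  Permutations on
    which the statistic is undefined are dropped (with a warning) and the
    denominator adjusted.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    stat = (lambda r: r.metrics[statistic]) if isinstance(statistic, str) else statistic
    observed = stat(loo_predict(features, labels, confounds, C))
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=bool)
    perm_stats = []
    dropped = 0
    for _ in range(n_permutations):
        try:
            s = stat(loo_predict(features, rng.permutation(y), confounds, C))
        except ValueError:
            s = float("nan")
        if np.isnan(s):
            dropped += 1
        else:
            perm_stats.append(s)
    if dropped:
        warnings.warn(f"{dropped} permutation(s) dropped (undefined statistic)")
    perm_stats = np.asarray(perm_stats)
    return float((1 + np.sum(perm_stats >= observed)) / (1 + len(perm_stats)))


def roi_prediction_table(map_volumes: dict[str, list[Volume]], labels, confounds,
                         roi_sets: dict[str, tuple[str, Volume]],
                         C: float = 1.0,
                         n_permutations: int = 0, seed: int = 0) -> pd.DataFrame:
    """One prediction row per (analysis name -> (map type, mask)) entry.

    ``roi_sets`` maps a row name to the input map type and the mask volume
    (whole-brain or atlas ROI union).  Set ``n_permutations`` > 0 to append
    permutation p-values for balanced accuracy and both class accuracies.
    """
    rows = []
    for row_name, (map_name, mask) in roi_sets.items():
        if map_name not in map_volumes:
            raise KeyError(f"unknown map type {map_name!r}")
        fm = extract_features(map_volumes[map_name], mask)
        res = loo_predict(fm, labels, confounds, C)
        row = {"analysis": row_name, "map": map_name, **res.metrics}
        if n_permutations:
            for stat in ("balanced_accuracy", "sensitivity", "specificity"):
                row[f"p_{stat}"] = permutation_pvalue(
                    fm, labels, confounds, stat, n_permutations, seed, C)
        rows.append(row)
    cols = ["analysis", "map", "total_accuracy", "balanced_accuracy",
            "sensitivity", "specificity", "ppv", "npv", "auc"]
    extra = [c for c in (rows[0] if rows else {}) if c not in cols]
    return pd.DataFrame(rows, columns=cols + extra if rows else cols)
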