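"""Longitudinal voxel-wise change: rate maps from divergence-map series.

Divergence maps express each time-point's anatomy as expansion/contraction
relative to the subject's average mid-point anatomy; an independent OLS line
per voxel over scan time turns the series into a *rate map* — the fractional
volume change per year at every voxel.  Tissue-weighted rates and
weight-normalised (warped-weighted-average, WWA) smoothing prepare the rate
maps for group statistics without diluting signal into unweighted regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import Volume, check_congruent
from .vbm import gaussian_smooth


@dataclass
class RateMap:
    slope: Volume  # fractional change / year
    intercept: Volume  # value at the mean scan time
    n_timepoints: int


def fit_voxel_rates(divergence_series: list[tuple[float, Volume]]) -> RateMap:
    """Independent per-voxel OLS fit of divergence on scan time."""
    if len(divergence_series) < 2:
        raise ValueError("need at least 2 time points")
    times = np.asarray([t for t, _ in divergence_series], dtype=float)
    if len(np.unique(times)) < 2:
        raise ValueError("need at least 2 distinct times")
    vols = [v for _, v in divergence_series]
    check_congruent(*vols)
    Y = np.stack([v.data for v in vols])  # (T, x, y, z)
    tc = times - times.mean()
    denom = np.sum(tc * tc)
    slope = np.tensordot(tc, Y - Y.mean(axis=0), axes=1) / denom
    intercept = Y.mean(axis=0)
    ref = vols[0]
    return RateMap(ref.like(slope), ref.like(intercept), len(times))


def tissue_weighted_rate(rate: RateMap, tissue: Volume) -> Volume:
    """Voxel-wise product of the rate slope with a tissue probability map."""
    check_congruent(rate.slope, tissue)
    return rate.slope.like(rate.slope.data * tissue.data)


def wwa_smooth(map_: Volume, weight: Volume, fwhm_mm: float,
               eps: float = 1e-6) -> Volume:
    """Weight-normalised Gaussian smoothing: smooth(f*w) / smooth(w).

    Voxels where the smoothed weight falls below ``eps`` are masked to 0
    (no supporting tissue within kernel reach).
    """
    check_congruent(map_, weight)
    if np.any(weight.data < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weight.data > 0):
        raise ValueError("weight map is identically zero")
    num = gaussian_smooth(map_.like(map_.data * weight.data), fwhm_mm)
    den = gaussian_smooth(weight, fwhm_mm)
    supported = den.data >= eps
    out = np.zeros(map_.shape)
    out[supported] = num.data[supported] / den.data[supported]
    return map_.like(out)


def roi_mean_rate(rate: RateMap, mask: Volume) -> float:
    """Mean slope over a binary ROI mask (e.g. hippocampal atrophy rate)."""
    check_congruent(rate.slope, mask)
    idx = mask.data > 0
    if not idx.any():
        raise ValueError("empty ROI mask")
    return float(rate.slope.data[idx].mean())
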