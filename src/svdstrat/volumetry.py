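"""Whole-brain MRI parameters: tissue volumes, TCV, TIV, SVDp and rates.

Total cerebral volume (TCV) is the sum of grey matter, white matter and WMH
volumes at tissue-probability threshold >= 0.2; total intracranial volume
(TIV) adds CSF.  SVDp, the composite vascular-burden marker, is the
percentage ratio of WMH volume to TCV — combining lesion load and atrophy so
that a shrinking brain cannot mask static WMH.  Annualised rates of change
are least-squares slopes over all available time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import TissueSet, Volume

#: tissue-probability threshold used for all volumetric counts
DEFAULT_THRESHOLD = 0.2
#: per-subject WMH binarisation threshold (manually chosen in practice;
#: a fixed stand-in here)
DEFAULT_WMH_THRESHOLD = 0.5


@dataclass
class VolumetricsRow:
    gm_mm3: float
    wm_mm3: float
    csf_mm3: float
    wmh_mm3: float
    lacune_mm3: float
    tcv_mm3: float
    tiv_mm3: float
    svdp_percent: float


def tissue_volume(tissue_map: Volume, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Volume in mm^3 of voxels whose tissue probability meets ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    count = int(np.count_nonzero(tissue_map.data >= threshold))
    return count * tissue_map.voxel_volume_mm3


def total_volumes(gm_mm3: float, wm_mm3: float, wmh_mm3: float,
                  csf_mm3: float) -> tuple[float, float]:
    """(TCV, TIV) from component volumes: TCV = GM+WM+WMH, TIV = TCV+CSF."""
    for name, v in (("gm", gm_mm3), ("wm", wm_mm3), ("wmh", wmh_mm3), ("csf", csf_mm3)):
        if v < 0:
            raise ValueError(f"negative {name} volume {v}")
    tcv = gm_mm3 + wm_mm3 + wmh_mm3
    return tcv, tcv + csf_mm3


def svdp(wmh_mm3: float, tcv_mm3: float) -> float:
    """SVDp: percentage ratio of WMH volume to total cerebral volume."""
    if tcv_mm3 <= 0:
        raise ZeroDivisionError("SVDp undefined for non-positive TCV")
    return 100.0 * wmh_mm3 / tcv_mm3


def annualized_rate(values, times) -> float:
    """Ordinary-least-squares slope of ``values`` on ``times`` (per year)."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("values and times must be 1-D and aligned")
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points")
    tc = t - t.mean()
    return float(np.sum(tc * (y - y.mean())) / np.sum(tc * tc))


def subject_volumetrics(tissues: TissueSet,
                        threshold: float = DEFAULT_THRESHOLD,
                        wmh_threshold: float = DEFAULT_WMH_THRESHOLD) -> VolumetricsRow:
    """Full volumetric row for one subject's tissue set."""
    gm = tissue_volume(tissues.gm, threshold)
    wm = tissue_volume(tissues.wm, threshold)
    csf = tissue_volume(tissues.csf, threshold)
    wmh = tissue_volume(tissues.wmh, wmh_threshold)
    lac = tissue_volume(tissues.lacunes, 0.5)
    tcv, tiv = total_volumes(gm, wm, wmh, csf)
    return VolumetricsRow(
        gm_mm3=gm, wm_mm3=wm, csf_mm3=csf, wmh_mm3=wmh, lacune_mm3=lac,
        tcv_mm3=tcv, tiv_mm3=tiv,
        svdp_percent=svdp(wmh, tcv) if tcv > 0 else float("nan"),
    )
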