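"""Lacune overlap maps, atlas-ROI incidence tables and rater reliability.

Incidence follows the reporting rule used for strategic-lacune analyses: a
subject counts for a region only when the intersecting lacune volume exceeds
10 mm^3 (strict), and a region is flagged as differentially affected when
the convertor-minus-non-convertor incidence difference reaches 9 percentage
points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import Atlas, Volume, check_congruent

MIN_LACUNE_MM3 = 10.0
FLAG_DIFFERENCE_PERCENT = 9.0


@dataclass
class ReliabilityReport:
    """Inter/intra-rater agreement metrics for paired volume measurements."""

    sem_mm3: float  # standard error of measurement, SD(a-b)/sqrt(2)
    mean_variability_percent: float  # mean of 100*|a-b| / pair mean
    variability_sd_percent: float
    icc_consistency: float  # Pearson correlation of the two raters
    icc_agreement: float  # ICC(2,1), two-way random, absolute agreement
    n_pairs: int


def overlap_map(masks: list[Volume]) -> Volume:
    """Voxel-wise count of subjects with a lacune at each voxel."""
    if not masks:
        raise ValueError("overlap_map requires at least one mask")
    check_congruent(*masks)
    for i, m in enumerate(masks):
        if not np.isin(m.data, (0.0, 1.0)).all():
            raise ValueError(f"mask {i} is not binary")
    return masks[0].like(np.sum([m.data for m in masks], axis=0))


def roi_incidence(lacune_masks: list[Volume], atlas: Atlas, groups: list[str],
                  min_volume_mm3: float = MIN_LACUNE_MM3,
                  flag_difference: float = FLAG_DIFFERENCE_PERCENT) -> pd.DataFrame:
    """Per-region, per-group percentage of subjects with a lacune > 10 mm^3.

    Returns one row per atlas region with columns ``<group>_percent`` for
    each group, ``difference`` (convertor minus non-convertor when both
    present, else first minus second) and a ``flagged`` column marking
    differences >= 9 percentage points.
    """
    if len(lacune_masks) != len(groups):
        raise ValueError("one group label per mask required")
    known = ("preVaD", "non-convertor")
    unknown = sorted(set(groups) - set(known))
    if unknown:
        raise ValueError(f"unknown group label(s): {unknown}")
    group_names = [g for g in known if g in groups]
    vol = Volume(np.zeros(atlas.labels.shape), atlas.voxel_size_mm, atlas.space_tag)
    check_congruent(vol, *lacune_masks)
    voxel_vol = lacune_masks[0].voxel_volume_mm3
    rows = []
    for lab, region in sorted(atlas.names.items()):
        roi = atlas.labels == lab
        row: dict[str, object] = {"region": region}
        for g in group_names:
            members = [m for m, gg in zip(lacune_masks, groups) if gg == g]
            hit = [
                float(np.sum(m.data[roi])) * voxel_vol > min_volume_mm3
                for m in members
            ]
            row[f"{g}_percent"] = 100.0 * np.mean(hit) if members else np.nan
        if len(group_names) == 2:
            row["difference"] = row[f"{group_names[0]}_percent"] - row[f"{group_names[1]}_percent"]
            row["flagged"] = abs(row["difference"]) >= flag_difference
        rows.append(row)
    return pd.DataFrame(rows)


def rater_reliability(volumes_a, volumes_b) -> ReliabilityReport:
    """Agreement statistics between two raters' paired volume series.

    Pairs with zero total volume are dropped with a warning (relative
    variability is undefined there).
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D series required")
    keep = (a + b) > 0
    if not keep.all():
        warnings.warn(f"dropping {int(np.sum(~keep))} pair(s) with zero total volume")
        a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 usable pairs")
    diff = a - b
    sem = float(np.std(diff, ddof=1) / np.sqrt(2.0))
    rel = 200.0 * np.abs(diff) / (a + b)
    if np.std(a) == 0 or np.std(b) == 0:
        icc_c = 1.0 if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.allclose(a, b) else 0.0
    else:
        icc_c = float(np.corrcoef(a, b)[0, 1])
    return ReliabilityReport(
        sem_mm3=sem,
        mean_variability_percent=float(np.mean(rel)),
        variability_sd_percent=float(np.std(rel, ddof=1)),
        icc_consistency=icc_c,
        icc_agreement=icc_two_way_random(a, b),
        n_pairs=len(a),
    )


def icc_two_way_random(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares of the n x 2 rating table:
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0  # all ratings identical: perfect agreement
    return float((msr - mse) / denom)
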