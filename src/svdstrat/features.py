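"""Subjects x in-mask-voxels feature matrices shared by the GLM, the SVM
decoder and the subtyping pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import Volume, check_congruent


@dataclass
class FeatureMatrix:
    """Subject-by-voxel value matrix together with its defining mask.

    Column order is the lexicographic (C-order) index of in-mask voxels, so
    matrices built from the same mask are column-aligned.
    """

    values: np.ndarray  # (n_subjects, n_voxels)
    mask: Volume  # binary
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (subjects x voxels)")
        n_vox = int(np.count_nonzero(self.mask.data))
        if self.values.shape[1] != n_vox:
            raise ValueError(
                f"{self.values.shape[1]} columns but {n_vox} in-mask voxels")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("one subject id per row required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def scatter(self, row_values: np.ndarray, fill: float = 0.0) -> Volume:
        """Place a per-voxel vector back onto the template grid."""
        out = np.full(self.mask.shape, fill, dtype=np.float64)
        out[self.mask.data > 0] = row_values
        return self.mask.like(out)


def extract_features(volumes: list[Volume], mask: Volume,
                     subject_ids: list[str] | None = None) -> FeatureMatrix:
    """Stack each subject's in-mask voxel values into a feature matrix."""
    if not np.any(mask.data > 0):
        raise ValueError("empty feature mask")
    check_congruent(mask, *volumes)
    idx = mask.data > 0
    values = np.stack([v.data[idx] for v in volumes])
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(volumes))]
    return FeatureMatrix(values, mask, list(subject_ids))
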