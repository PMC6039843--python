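"""Anatomical endophenotype discovery within the convertor group.

Subjects' in-mask Jacobian-determinant vectors are condensed into a
subject-by-subject Pearson correlation matrix; the Euclidean distances
between the rows of that correlation matrix feed agglomerative Ward-linkage
clustering (the Ward.D2 convention: squared-distance updates on Euclidean
inputs).  Cutting the dendrogram at k groups (default 4, the number chosen
by visual inspection in the motivating analysis) yields the anatomical
subtypes, which are then summarised against demographics, volumetrics,
cognition and the SVM's per-subject predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .features import FeatureMatrix


@dataclass
class LinkageTree:
    """Ward merge history in scipy linkage form plus leaf ids."""

    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, size
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def subject_similarity(features: FeatureMatrix,
                       one_minus_r: bool = False) -> np.ndarray:
    """Subject distance matrix from pairwise Pearson correlations.

    Default (literal) construction: correlate every pair of subjects' voxel
    vectors, then take Euclidean distances between rows of the resulting
    correlation matrix (self-correlation entries included).  With
    ``one_minus_r=True`` the alternative 1-r dissimilarity is returned.
    """
    V = features.values
    if V.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if V.shape[1] < 2:
        raise ValueError("need at least 2 voxels")
    sd = V.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if len(flat):
        raise ValueError(
            f"zero-variance voxel vector for subject(s) "
            f"{[features.subject_ids[i] for i in flat]}")
    R = np.corrcoef(V)
    if one_minus_r:
        D = 1.0 - R
        np.fill_diagonal(D, 0.0)
        return D
    diff = R[:, None, :] - R[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def ward_linkage(distances: np.ndarray,
                 leaf_ids: list[str] | None = None) -> LinkageTree:
    """Ward minimum-variance agglomeration of a precomputed distance matrix."""
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("square distance matrix required")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distances must be non-negative with zero diagonal")
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    ids = leaf_ids if leaf_ids is not None else [f"s{i:03d}" for i in range(D.shape[0])]
    return LinkageTree(Z, list(ids))


def cut_tree(tree: LinkageTree, k: int = 4) -> np.ndarray:
    """Cluster labels 1..k, numbered by dendrogram left-to-right order."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    raw = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        warnings.warn(f"tied merge heights: obtained {len(np.unique(raw))} "
                      f"clusters instead of {k} (earlier merge wins)")
    # renumber by first appearance in dendrogram leaf order
    order = hierarchy.leaves_list(tree.merges)
    mapping: dict[int, int] = {}
    for leaf in order:
        mapping.setdefault(int(raw[leaf]), len(mapping) + 1)
    return np.asarray([mapping[int(c)] for c in raw])


def subgroup_summary(labels: np.ndarray, cohort_df: pd.DataFrame,
                     correct_predicted: np.ndarray | None = None,
                     hippo_rates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-subtype summary table (means and SDs of every numeric column).

    ``cohort_df`` carries one row per clustered subject (demographics,
    volumetrics, cognition, time to onset); ``correct_predicted`` flags
    subjects the SVM classified correctly; ``hippo_rates`` are per-subject
    mean hippocampal atrophy rates.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort_df):
        raise ValueError("one label per cohort row required")
    df = cohort_df.copy()
    if correct_predicted is not None:
        df["correct_predicted"] = np.asarray(correct_predicted, dtype=float)
    if hippo_rates is not None:
        df["hippocampal_rate"] = np.asarray(hippo_rates, dtype=float)
    rows = []
    for g in sorted(set(labels.tolist())):
        sel = df[labels == g]
        if len(sel) == 0:
            raise ValueError(f"empty subgroup {g}")
        row: dict[str, float] = {"group": g, "n": len(sel)}
        if "correct_predicted" in sel:
            row["correct_predicted_percent"] = 100.0 * sel["correct_predicted"].mean()
        for col in sel.columns:
            if col in ("correct_predicted",) or not pd.api.types.is_numeric_dtype(sel[col]):
                continue
            row[f"{col}_mean"] = float(sel[col].mean())
            row[f"{col}_sd"] = float(sel[col].std(ddof=1)) if len(sel) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
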