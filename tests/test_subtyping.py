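"""Correlation-row distances, Ward linkage, tree cuts and subgroup tables."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from svdstrat.features import FeatureMatrix
from svdstrat.io_core import Volume
from svdstrat.subtyping import (
    cut_tree,
    subgroup_summary,
    subject_similarity,
    ward_linkage,
)


def _fm(values):
    values = np.asarray(values, dtype=float)
    n_vox = values.shape[1]
    side = int(np.ceil(n_vox ** (1 / 3)))
    mask = np.zeros((side, side, side))
    mask.flat[:n_vox] = 1.0
    return FeatureMatrix(values, Volume(mask), [f"s{i:03d}" for i in range(len(values))])


class TestSubjectSimilarity:
    def test_identical_subjects_have_zero_distance(self, rng):
        v = rng.standard_normal(20)
        fm = _fm([v, v, rng.standard_normal(20)])
        D = subject_similarity(fm)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[0, 2] > 0

    def test_identity_correlation_rows_are_sqrt2_apart(self):
        # three exactly uncorrelated subjects: correlation matrix = I,
        # and rows of I are sqrt(2) apart
        v1 = np.array([1.0, 1.0, -1.0, -1.0])
        v2 = np.array([1.0, -1.0, 1.0, -1.0])
        v3 = np.array([1.0, -1.0, -1.0, 1.0])
        D = subject_similarity(_fm([v1, v2, v3]))
        for i, j in combinations(range(3), 2):
            assert D[i, j] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_matches_double_loop_brute_force(self, rng):
        V = rng.standard_normal((5, 30))
        D = subject_similarity(_fm(V))
        R = np.array([[np.corrcoef(V[i], V[j])[0, 1] for j in range(5)]
                      for i in range(5)])
        for i in range(5):
            for j in range(5):
                oracle = np.sqrt(np.sum((R[i] - R[j]) ** 2))
                assert D[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_per_subject_affine_rescaling_is_invariant(self, rng):
        V = rng.standard_normal((4, 25))
        D1 = subject_similarity(_fm(V))
        V2 = V * rng.uniform(0.5, 2.0, (4, 1)) + rng.uniform(-3, 3, (4, 1))
        D2 = subject_similarity(_fm(V2))
        np.testing.assert_allclose(D1, D2, atol=1e-10)

    def test_zero_variance_subject_is_named(self, rng):
        V = rng.standard_normal((3, 10))
        V[1] = 7.0
        with pytest.raises(ValueError, match="s001"):
            subject_similarity(_fm(V))


def _pairwise_euclid(points):
    n = len(points)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.linalg.norm(points[i] - points[j])
    return D


class TestWardLinkage:
    def test_tight_far_pairs_merge_first(self):
        points = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
        tree = ward_linkage(_pairwise_euclid(points))
        first_two = {frozenset(tree.merges[0, :2].astype(int)),
                     frozenset(tree.merges[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_merge_heights_weakly_increase(self, rng):
        points = rng.standard_normal((12, 3))
        tree = ward_linkage(_pairwise_euclid(points))
        heights = tree.merges[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_two_cluster_cut_matches_exhaustive_variance_search(self, seed):
        gen = np.random.default_rng(seed)
        points = np.vstack([gen.normal(0.0, 0.5, (3, 2)),
                            gen.normal((4.0, 0.0), 0.5, (3, 2))])
        points = points[gen.permutation(6)]
        tree = ward_linkage(_pairwise_euclid(points))
        labels = cut_tree(tree, 2)

        def wss(partition):
            total = 0.0
            for cluster in partition:
                if len(cluster) == 0:
                    return np.inf
                c = points[list(cluster)]
                total += np.sum((c - c.mean(axis=0)) ** 2)
            return total

        best, best_w = None, np.inf
        for assign in range(1, 2 ** 5):  # subject 0 fixed to cluster 0
            part = [{0}, set()]
            for i in range(5):
                part[(assign >> i) & 1].add(i + 1)
            w = wss(part)
            if w < best_w:
                best, best_w = part, w
        ward_part = [{i for i in range(6) if labels[i] == g} for g in (1, 2)]
        assert {frozenset(s) for s in ward_part} == {frozenset(s) for s in best}

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ward_linkage(D)


class TestCutTree:
    def test_k1_and_kn_extremes(self, rng):
        points = rng.standard_normal((7, 2))
        tree = ward_linkage(_pairwise_euclid(points))
        assert set(cut_tree(tree, 1)) == {1}
        assert sorted(cut_tree(tree, 7)) == list(range(1, 8))

    def test_labels_numbered_left_to_right(self, rng):
        points = np.array([[0.0], [0.2], [5.0], [5.2], [10.0], [10.2]])
        tree = ward_linkage(_pairwise_euclid(points))
        labels = cut_tree(tree, 3)
        # each tight pair shares a label and labels follow dendrogram order
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[4] == labels[5]
        from scipy.cluster import hierarchy

        order = hierarchy.leaves_list(tree.merges)
        seen = []
        for leaf in order:
            if labels[leaf] not in seen:
                seen.append(labels[leaf])
        assert seen == [1, 2, 3]

    def test_input_order_invariance_up_to_relabel(self, rng):
        from sklearn.metrics import adjusted_rand_score

        V = rng.standard_normal((10, 40))
        fm1 = _fm(V)
        perm = rng.permutation(10)
        fm2 = _fm(V[perm])
        l1 = cut_tree(ward_linkage(subject_similarity(fm1)), 3)
        l2 = cut_tree(ward_linkage(subject_similarity(fm2)), 3)
        assert adjusted_rand_score(l1[perm], l2) == 1.0

    def test_out_of_range_k_rejected(self, rng):
        tree = ward_linkage(_pairwise_euclid(rng.standard_normal((4, 2))))
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 5)


class TestSubgroupSummary:
    def test_identical_subjects_have_zero_sd(self):
        df = pd.DataFrame({"age": [70.0] * 6, "mmse": [27.0] * 6})
        out = subgroup_summary(np.array([1, 1, 1, 2, 2, 2]), df)
        assert (out["age_sd"] == 0).all()

    def test_hand_computed_ten_subject_fixture(self):
        age = [60, 62, 64, 70, 72, 74, 80, 82, 84, 86.0]
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 3])
        correct = np.array([1, 0, 1, 0, 0, 0, 1, 1, 1, 0])
        out = subgroup_summary(labels, pd.DataFrame({"age": age}), correct)
        assert out.loc[out.group == 1, "age_mean"].iloc[0] == pytest.approx(62.0)
        assert out.loc[out.group == 2, "age_mean"].iloc[0] == pytest.approx(72.0)
        assert out.loc[out.group == 3, "age_mean"].iloc[0] == pytest.approx(83.0)
        assert out.loc[out.group == 1, "age_sd"].iloc[0] == pytest.approx(2.0)
        assert out.loc[out.group == 1, "correct_predicted_percent"].iloc[0] == pytest.approx(200 / 3)
        assert out.loc[out.group == 3, "n"].iloc[0] == 4

    def test_vascular_subtype_has_highest_svdp(self, atlas, template, noiseless_effects):
        from svdstrat.synthetic import simulate_subject
        from svdstrat.volumetry import subject_volumetrics

        svdps = {}
        for subtype in (1, 4):
            s = simulate_subject(atlas, noiseless_effects, "preVaD", subtype, 3,
                                 template=template, longitudinal=False)
            svdps[subtype] = subject_volumetrics(s.tissues).svdp_percent
        assert svdps[1] > svdps[4]

    def test_label_row_mismatch_rejected(self):
        df = pd.DataFrame({"age": [1.0, 2.0]})
        with pytest.raises(ValueError):
            subgroup_summary(np.array([1, 1]), df.iloc[:1])
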