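"""Procrustes variance, permutation tests, hull areas and sum of variances."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from morphodisp import (
    LandmarkConfiguration,
    convex_hull_area,
    gpa,
    pairwise_pv_test,
    pca,
    procrustes_variance,
    sum_of_variances,
    weighted_hull_area,
)
from morphodisp.disparity import disparity_shares, hull_areas
from morphodisp.ordination import Ordination

from helpers import aligned_from_flat


def brute_force_hull_area(points):
    """Exhaustive oracle: a point is a hull vertex iff some half-plane through
    it contains all other points; area by shoelace on the angular-sorted vertices."""
    pts = np.asarray(points, float)
    n = len(pts)
    vertices = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            normal = np.array([-d[1], d[0]])
            side = (pts - pts[i]) @ normal
            if np.all(side <= 1e-12) or np.all(side >= -1e-12):
                vertices.append(i)
                break
    verts = pts[sorted(set(vertices))]
    centroid = verts.mean(axis=0)
    order = np.argsort(np.arctan2(*(verts - centroid).T[::-1]))
    v = verts[order]
    x, y = v[:, 0], v[:, 1]
    return abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2


class TestProcrustesVariance:
    def test_identical_shapes_zero(self):
        flat = np.tile(np.arange(8.0), (5, 1))
        assert procrustes_variance(aligned_from_flat(flat, 4))["all"] == 0.0

    def test_two_point_closed_form(self):
        # two specimens differing by d in one coordinate: PV = d^2/4
        d = 0.6
        a = np.zeros(8)
        b = a.copy()
        b[3] = d
        pv = procrustes_variance(aligned_from_flat([a, b], 4))["all"]
        assert pv == pytest.approx(d**2 / 4)

    def test_isotropic_noise_calibration(self):
        # post-GPA dimensionality: PV approx s^2 * (2k - 4)
        rng = np.random.default_rng(11)
        k, n, s = 12, 1000, 0.01
        base = rng.normal(size=(k, 2))
        base /= np.sqrt((base - base.mean(0)).var() * 2 * k)  # unit centroid size
        configs = [
            LandmarkConfiguration(f"s{i}", base + rng.normal(0, s, (k, 2))) for i in range(n)
        ]
        sample = gpa(configs)
        pv = procrustes_variance(sample)["all"]
        assert pv == pytest.approx(s**2 * (2 * k - 4), rel=0.10)

    def test_group_shares_sum_to_one(self, rng):
        flat = rng.normal(size=(30, 8))
        labels = rng.choice(["a", "b", "c"], size=30)
        pv = procrustes_variance(aligned_from_flat(flat, 4), labels)
        shares = disparity_shares(pv)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_whole_sample_consistency_with_score_variance(self, study_bundle):
        # PV (divisor n) equals summed per-axis score variance with divisor n
        configs, sliders, *_ = study_bundle
        sample = gpa(configs, sliders=sliders)
        ord = pca(sample)
        pv = procrustes_variance(sample)["all"]
        score_var = (ord.scores.var(axis=0, ddof=0)).sum()
        assert pv == pytest.approx(score_var, abs=1e-9)


class TestPairwisePVTest:
    def test_self_comparison_statistic_zero_p_one(self, rng):
        flat = rng.normal(size=(20, 6))
        labels = np.array(["g1"] * 10 + ["g2"] * 10)
        # duplicate one group under two labels: identical distributions
        flat[10:] = flat[:10]
        diff, p = pairwise_pv_test(aligned_from_flat(flat, 3), labels, n_perm=99, seed=0)
        assert diff.loc["g1", "g2"] == pytest.approx(0.0)
        assert p.loc["g1", "g2"] == pytest.approx(1.0)
        assert (np.diag(p) == 1).all()

    def test_matrix_symmetry_and_label_swap_invariance(self, rng):
        flat = rng.normal(size=(24, 6))
        labels = np.array(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        diff, p = pairwise_pv_test(aligned_from_flat(flat, 3), labels, n_perm=199, seed=5)
        assert np.allclose(diff, diff.T) and np.allclose(p, p.T)
        swapped = np.where(labels == "a", "b", np.where(labels == "b", "a", labels))
        diff2, p2 = pairwise_pv_test(aligned_from_flat(flat, 3), swapped, n_perm=199, seed=5)
        assert diff2.loc["a", "b"] == pytest.approx(diff.loc["a", "b"])

    def test_singleton_group_p_absent(self, rng):
        flat = rng.normal(size=(7, 6))
        labels = np.array(["solo"] + ["rest"] * 6)
        diff, p = pairwise_pv_test(aligned_from_flat(flat, 3), labels, n_perm=99, seed=0)
        assert np.isnan(p.loc["solo", "rest"])
        assert np.isfinite(diff.loc["solo", "rest"])

    def test_reproducible_given_seed(self, rng):
        flat = rng.normal(size=(20, 6))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        r1 = pairwise_pv_test(aligned_from_flat(flat, 3), labels, n_perm=199, seed=3)
        r2 = pairwise_pv_test(aligned_from_flat(flat, 3), labels, n_perm=199, seed=3)
        assert r1[1].equals(r2[1])

    def test_power_against_fourfold_variance_ratio(self):
        # two groups with 4x PV ratio, n=30 each: p < 0.05 in >= 90% of replicates
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 50
        for _ in range(n_rep):
            g1 = rng.normal(0, 1.0, size=(30, 10))
            g2 = rng.normal(0, 2.0, size=(30, 10))  # 4x the variance
            flat = np.vstack([g1, g2])
            labels = np.array(["a"] * 30 + ["b"] * 30)
            _, p = pairwise_pv_test(aligned_from_flat(flat, 5), labels, n_perm=199, rng=rng)
            rejections += p.loc["a", "b"] < 0.05
        assert rejections / n_rep >= 0.90


class TestConvexHullArea:
    def test_closed_forms(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5], [0.2, 0.8]])
        assert convex_hull_area(square) == pytest.approx(1.0)
        triangle = np.array([[0, 0], [2, 0], [0, 2]])
        assert convex_hull_area(triangle) == pytest.approx(2.0)

    def test_collinear_is_zero(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        assert convex_hull_area(pts) == 0.0

    def test_fewer_than_three_points_undefined(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            convex_hull_area(np.array([[0, 0], [1, 1]]))

    def test_matches_brute_force_and_scipy(self, rng):
        for _ in range(30):
            pts = rng.normal(size=(30, 2))
            area = convex_hull_area(pts)
            assert area == pytest.approx(brute_force_hull_area(pts), abs=1e-10)
            assert area == pytest.approx(ConvexHull(pts).volume, abs=1e-10)

    def test_invariant_to_ordering_and_rotation(self, rng):
        pts = rng.normal(size=(25, 2))
        area = convex_hull_area(pts)
        assert convex_hull_area(pts[rng.permutation(25)]) == pytest.approx(area, abs=1e-12)
        ang = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        assert convex_hull_area(pts @ R.T) == pytest.approx(area, abs=1e-9)


def make_ordination(scores, prop_variance=None):
    scores = np.asarray(scores, float)
    scores = scores - scores.mean(axis=0)
    n, m = scores.shape
    ev = scores.var(axis=0, ddof=1) if prop_variance is None else np.asarray(prop_variance, float)
    return Ordination(
        scores=scores,
        eigenvalues=ev,
        prop_variance=ev / ev.sum(),
        loadings=np.eye(m),
        mean_vector=np.zeros(m),
        specimen_ids=[f"s{i}" for i in range(n)],
    )


class TestWeightedHullArea:
    def test_rank_two_degenerates_to_plain_hull(self, rng):
        scores = np.zeros((12, 5))
        scores[:, :2] = rng.normal(size=(12, 2))
        ord = make_ordination(scores)
        labels = ["g"] * 12
        w = weighted_hull_area(ord, labels, n_pcs=5)["g"]
        plain = hull_areas(ord, labels)["g"]
        # all variance on PCs 1-2: that pair has weight 1, every other pair area 0
        assert w == pytest.approx(plain)

    def test_homogeneity_degree_two(self, rng):
        scores = rng.normal(size=(15, 5))
        ord1 = make_ordination(scores)
        ord2 = make_ordination(2 * scores, prop_variance=ord1.prop_variance * ord1.eigenvalues.sum())
        labels = ["g"] * 15
        w1 = weighted_hull_area(ord1, labels)["g"]
        w2 = weighted_hull_area(ord2, labels)["g"]
        assert w2 == pytest.approx(4 * w1)

    def test_matches_independent_pairwise_recomputation(self, rng):
        scores = rng.normal(size=(20, 5)) * np.array([3, 2.2, 1.5, 1.0, 0.5])
        ord = make_ordination(scores)
        labels = ["g"] * 20
        got = weighted_hull_area(ord, labels, n_pcs=5)["g"]
        expected = 0.0
        for i, j in combinations(range(5), 2):
            expected += ConvexHull(scores[:, [i, j]]).volume * (
                ord.prop_variance[i] + ord.prop_variance[j]
            )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_small_group_absent(self, rng):
        scores = rng.normal(size=(5, 5))
        labels = ["small"] * 2 + ["big"] * 3
        out = weighted_hull_area(make_ordination(scores), labels)
        assert "small" not in out and "big" in out

    def test_normalized_option_divides_by_total_weight(self, rng):
        scores = rng.normal(size=(15, 5))
        ord = make_ordination(scores)
        labels = ["g"] * 15
        raw = weighted_hull_area(ord, labels, normalize=False)["g"]
        norm = weighted_hull_area(ord, labels, normalize=True)["g"]
        pairs = list(combinations(range(5), 2))
        total_w = sum(ord.prop_variance[i] + ord.prop_variance[j] for i, j in pairs)
        assert norm == pytest.approx(raw / total_w)


class TestSumOfVariances:
    def test_full_sample_equals_eigenvalue_sum(self, study_bundle):
        configs, sliders, *_ = study_bundle
        ord = pca(gpa(configs, sliders=sliders))
        assert sum_of_variances(ord.scores) == pytest.approx(ord.eigenvalues.sum(), abs=1e-9)

    def test_duplicated_shape_zero(self):
        assert sum_of_variances(np.tile([1.0, 2.0, 3.0], (4, 1))) == 0.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            sum_of_variances(np.array([[1.0, 2.0]]))

    def test_subset_equals_coordinate_space_total_variance(self, study_bundle, rng):
        configs, sliders, *_ = study_bundle
        sample = gpa(configs, sliders=sliders)
        ord = pca(sample)
        flat = sample.flattened()
        for _ in range(5):
            idx = rng.choice(sample.n, size=10, replace=False)
            sv = sum_of_variances(ord.scores[idx])
            sub = flat[idx]
            direct = ((sub - sub.mean(axis=0)) ** 2).sum() / (len(idx) - 1)
            assert sv == pytest.approx(direct, abs=1e-9)


class TestParameterRecovery:
    def test_planted_noise_ratio_recovered(self):
        # groups with noise sds (s, 2s) -> PV ratio approx 4 at n=200/group
        rng = np.random.default_rng(29)
        k, n, s = 12, 200, 0.01
        base = rng.normal(size=(k, 2))
        base /= np.sqrt(((base - base.mean(0)) ** 2).sum())
        configs = [
            LandmarkConfiguration(f"a{i}", base + rng.normal(0, s, (k, 2))) for i in range(n)
        ] + [
            LandmarkConfiguration(f"b{i}", base + rng.normal(0, 2 * s, (k, 2))) for i in range(n)
        ]
        sample = gpa(configs)
        labels = ["low"] * n + ["high"] * n
        pv = procrustes_variance(sample, labels)
        ratio = pv["high"] / pv["low"]
        assert 3.4 <= ratio <= 4.6
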