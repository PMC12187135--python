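"""Permutation partial correlations, Holm, bend correlation, cluster test,
signed-rank z."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from blinksdt import (MetricSeries, bend_correlation, cluster_permutation, holm_adjust,
                      normalize_per_participant, partial_correlation_perm, signed_rank_z)


def series(mat, name="m"):
    return MetricSeries(np.asarray(mat, dtype=float), name=name)


class TestNormalizePerParticipant:
    def test_constant_row(self):
        out = normalize_per_participant(series([[1, 1, 1, 1, 1]]))
        np.testing.assert_allclose(out.matrix, 0.2)

    def test_hand_arithmetic_row(self):
        out = normalize_per_participant(series([[2, 1, 1, 3, 3]]))
        np.testing.assert_allclose(out.matrix, [[0.2, 0.1, 0.1, 0.3, 0.3]])

    def test_idempotent_fixed_point(self):
        once = normalize_per_participant(series([[2, 1, 1, 3, 3], [5, 0, 0, 0, 5]]))
        twice = normalize_per_participant(once)
        np.testing.assert_allclose(twice.matrix, once.matrix)

    def test_near_zero_sum_rows_excluded(self):
        out = normalize_per_participant(series([[1, -1, 0, 0, 0], [1, 1, 1, 1, 1]]))
        assert np.all(np.isnan(out.matrix[0]))
        np.testing.assert_allclose(out.matrix[1], 0.2)
        with pytest.raises(ValueError):
            normalize_per_participant(series([[1, -1, 0, 0, 0]]))


class TestPartialCorrelationPerm:
    def _cohort(self, seed, n=18):
        rng = np.random.default_rng(seed)
        return (rng.uniform(0.5, 1.5, (n, 5)), rng.uniform(0.5, 1.5, (n, 5)),
                rng.uniform(0.5, 1.5, (n, 5)))

    def test_perfect_association_hits_p_floor(self):
        x, _, z = self._cohort(0)
        r, p = partial_correlation_perm(series(x), series(x.copy()), series(z),
                                        n_perm=500, seed=1)
        assert r > 0.99
        assert p == pytest.approx(1 / 501, abs=1e-9)

    def test_orthogonal_control_reduces_to_plain_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        y = 0.6 * x + 0.8 * rng.standard_normal(40)
        # control exactly orthogonal to span{1, x, y}
        q, _ = np.linalg.qr(np.column_stack([np.ones(40), x, y]))
        z = rng.standard_normal(40)
        z = z - q @ (q.T @ z)
        xs = series(x.reshape(8, 5))
        ys = series(y.reshape(8, 5))
        zs = series(z.reshape(8, 5))
        r, _ = partial_correlation_perm(xs, ys, zs, n_perm=10, seed=0, normalize=False)
        assert r == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-10)

    def test_type_one_error_calibrated(self):
        # independent metrics: rejection rate at alpha = .05 stays near nominal
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            x, y, z = self._cohort(100 + rep)
            _, p = partial_correlation_perm(series(x), series(y), series(z),
                                            n_perm=200, seed=rep)
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_too_few_points_rejected(self):
        one = series(np.full((1, 5), np.nan))
        with pytest.raises(ValueError):
            partial_correlation_perm(one, one, one, n_perm=10)


class TestHolmAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])

    def test_hand_step_down(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty_list(self):
        assert len(holm_adjust([])) == 0

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dominates_raw_and_bounded_by_bonferroni(self, pvals):
        adj = holm_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= np.minimum(len(p) * p, 1.0) + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestBendCorrelation:
    def test_identity_and_sign_flip(self):
        x = np.array([0.1, 0.5, 1.2, 2.0, 3.3, 4.1, 5.0, 6.6])
        assert bend_correlation(x, x) == pytest.approx(1.0)
        assert bend_correlation(x, -x) == pytest.approx(-1.0)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(15)
        y = 0.5 * x + rng.standard_normal(15)
        assert bend_correlation(x, y) == pytest.approx(bend_correlation(y, x), abs=1e-14)

    def test_matches_independent_reference_with_outlier(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10)
        y = 0.8 * x + 0.3 * rng.standard_normal(10)
        y[0] = 40.0  # gross outlier
        ours = bend_correlation(x, y, bend=0.2)
        ref = pingouin.corr(x, y, method="percbend")["r"].iloc[0]
        assert ours == pytest.approx(ref, abs=1e-10)
        # and robustness: the outlier barely moves the estimate
        clean = bend_correlation(x, np.where(np.arange(10) == 0, y, y), bend=0.2)
        assert abs(ours - clean) < 1e-12

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            assert -1.0 <= bend_correlation(x, y) <= 1.0

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            bend_correlation(np.ones(10), np.arange(10.0))


class TestClusterPermutation:
    def test_planted_effect_detected_at_p_floor(self):
        # 16 participants keep the chance of an (anti)identity sign flip -- which
        # would tie the observed statistic -- negligible over 500 draws
        rng = np.random.default_rng(6)
        maps = rng.standard_normal((16, 20, 10))
        maps[:, 5:10, 2:6] += 2.0  # Cohen's d = 2 rectangle
        clusters = cluster_permutation(maps, n_perm=500, seed=0)
        assert clusters
        top = clusters[0]
        assert top.sign > 0 and top.p == pytest.approx(1 / 501, abs=1e-9)
        # the detected cluster covers most of the planted rectangle
        planted = np.zeros((20, 10), dtype=bool)
        planted[5:10, 2:6] = True
        assert (top.mask & planted).sum() >= 0.8 * planted.sum()

    def test_sign_flip_mirrors_clusters(self):
        rng = np.random.default_rng(7)
        maps = rng.standard_normal((10, 12, 8))
        maps[:, 2:5, 2:5] += 1.5
        a = cluster_permutation(maps, n_perm=200, seed=1)
        b = cluster_permutation(-maps, n_perm=200, seed=1)
        assert len(a) == len(b)
        np.testing.assert_array_equal(a[0].mask, b[0].mask)
        assert a[0].stat == pytest.approx(-b[0].stat)
        assert a[0].p == b[0].p

    def test_constant_zero_input_has_no_clusters(self):
        assert cluster_permutation(np.zeros((8, 10, 6)), n_perm=100, seed=0) == []

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((4, 10, 6)))


class TestSignedRankZ:
    def test_all_zero_differences_flagged_undefined(self):
        x = np.arange(8.0)
        z, p = signed_rank_z(x, x.copy())
        assert np.isnan(z) and np.isnan(p)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(15)
        y = x + rng.standard_normal(15)
        z1, p1 = signed_rank_z(x, y)
        z2, p2 = signed_rank_z(y, x)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_enumeration_oracle_eight_pairs(self):
        # hand-listed differences: d = x - y = [1, -2, 3, -4, 5, 6, -7, 8]
        x = np.array([2.0, 1.0, 4.0, 0.0, 6.0, 7.0, 0.0, 9.0])
        y = np.array([1.0, 3.0, 1.0, 4.0, 1.0, 1.0, 7.0, 1.0])
        # ranks of |d| are 1..8; positive ranks: 1, 3, 5, 6, 8 -> W+ = 23
        # mu = 8*9/4 = 18; var = 8*9*17/24 = 51; z = 5 / sqrt(51)
        z, p = signed_rank_z(x, y)
        assert z == pytest.approx(5.0 / np.sqrt(51.0), abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(5.0 / np.sqrt(51.0)), abs=1e-12)

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        y = x + 0.4 + rng.standard_normal(30)
        z, p = signed_rank_z(x, y)
        ref = stats.wilcoxon(x, y, correction=False, method="approx")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
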