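import numpy as np
import pytest

from qccmap.cell_table import ValidationError
from qccmap.spatial_stats import (
    ClusterIndexConfig,
    NoQCCError,
    build_neighbor_index,
    cluster_index_test,
    empirical_p,
    exact_null,
    neighbor_fraction,
    permutation_null,
    qcc_ci,
    qcc_ci_bruteforce,
)


LINE_XY = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0], [4.0, 0.0]])
LINE_LABELS = np.array([True, True, False, False, False])
LINE_CONFIG = ClusterIndexConfig(k=2, window=500.0, B=10, seed=0)


class TestNeighborFraction:
    def test_collinear_hand_geometry(self):
        # focal at x=0: 2 nearest are x=1 (QCC) and x=2 (other) -> 0.5
        frac = neighbor_fraction(LINE_XY, 0, LINE_LABELS, LINE_CONFIG)
        assert frac == 0.5

    def test_too_few_candidates_discarded(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0]])  # k=2 needs 2 non-focal cells
        labels = np.array([True, False])
        assert neighbor_fraction(xy, 0, labels, LINE_CONFIG) is None

    def test_window_censors_candidates(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [600.0, 0.0]])
        labels = np.array([True, False, False])
        cfg = ClusterIndexConfig(k=2, window=500.0)
        assert neighbor_fraction(xy, 0, labels, cfg) is None  # x=600 outside box

    def test_saturation_all_qcc(self, rng):
        xy = rng.uniform(0, 100, size=(30, 2))
        labels = np.ones(30, dtype=bool)
        cfg = ClusterIndexConfig(k=5, window=500.0)
        assert neighbor_fraction(xy, 0, labels, cfg) == 1.0

    def test_non_qcc_focal_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_fraction(LINE_XY, 2, LINE_LABELS, LINE_CONFIG)


class TestQccCi:
    def test_collinear_average(self):
        # focal x=0 -> 0.5; focal x=1 -> neighbors x=0 (QCC) and x=2 -> 0.5
        res = qcc_ci(LINE_XY, LINE_LABELS, LINE_CONFIG)
        assert res.qcc_ci == 0.5
        assert res.n_focal_retained == 2
        assert res.n_focal_discarded == 0

    def test_all_qcc_dense_field(self, rng):
        xy = rng.uniform(0, 100, size=(50, 2))
        res = qcc_ci(xy, np.ones(50, bool), ClusterIndexConfig(k=10, window=500.0))
        assert res.qcc_ci == 1.0

    def test_zero_qcc_distinct_error(self):
        with pytest.raises(NoQCCError):
            qcc_ci(LINE_XY, np.zeros(5, bool), LINE_CONFIG)

    def test_all_discarded_flagged_undefined(self):
        xy = np.array([[0.0, 0.0], [2000.0, 2000.0]])
        labels = np.array([True, True])
        res = qcc_ci(xy, labels, ClusterIndexConfig(k=1, window=500.0))
        assert not res.defined
        assert np.isnan(res.qcc_ci)
        assert res.n_focal_discarded == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        xy = rng.uniform(0, 1500, size=(n, 2))
        labels = rng.random(n) < 0.1
        if not labels.any():
            labels[0] = True
        cfg = ClusterIndexConfig(k=int(rng.integers(1, 25)), window=float(rng.uniform(100, 800)))
        fast = qcc_ci(xy, labels, cfg)
        slow = qcc_ci_bruteforce(xy, labels, cfg)
        assert fast.defined == slow.defined
        assert fast.n_focal_discarded == slow.n_focal_discarded
        if fast.defined:
            np.testing.assert_allclose(np.sort(fast.fractions), np.sort(slow.fractions))
            assert fast.qcc_ci == pytest.approx(slow.qcc_ci)

    def test_translation_and_scaling_invariance(self, rng):
        n = 120
        xy = rng.uniform(0, 1000, size=(n, 2))
        labels = rng.random(n) < 0.15
        labels[0] = True
        cfg = ClusterIndexConfig(k=8, window=300.0)
        base = qcc_ci(xy, labels, cfg)
        shifted = qcc_ci(xy + [123.0, -77.0], labels, cfg)
        assert shifted.qcc_ci == pytest.approx(base.qcc_ci)
        scaled = qcc_ci(xy * 4.0, labels, ClusterIndexConfig(k=8, window=1200.0))
        assert scaled.qcc_ci == pytest.approx(base.qcc_ci)

    def test_rotation_invariance_with_unconstraining_window(self, rng):
        # with the window wider than the whole field the box filter is inert
        # and the index depends only on Euclidean distances
        n = 100
        xy = rng.uniform(0, 100, size=(n, 2))
        labels = rng.random(n) < 0.2
        labels[0] = True
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        cfg = ClusterIndexConfig(k=10, window=10_000.0)
        assert qcc_ci(xy @ rot.T, labels, cfg).qcc_ci == pytest.approx(
            qcc_ci(xy, labels, cfg).qcc_ci
        )


class TestPermutationNull:
    def test_degenerate_full_draw(self, rng):
        xy = rng.uniform(0, 50, size=(20, 2))
        cfg = ClusterIndexConfig(k=3, window=500.0, B=25, seed=1)
        scores, n_undef = permutation_null(xy, 20, cfg)
        assert n_undef == 0
        np.testing.assert_allclose(scores, 1.0)

    def test_seed_determinism(self, rng):
        xy = rng.uniform(0, 500, size=(80, 2))
        cfg = ClusterIndexConfig(k=5, window=500.0, B=50, seed=42)
        s1, _ = permutation_null(xy, 10, cfg)
        s2, _ = permutation_null(xy, 10, cfg)
        np.testing.assert_array_equal(s1, s2)

    def test_n_qcc_exceeding_population_errors(self, rng):
        xy = rng.uniform(0, 50, size=(10, 2))
        with pytest.raises(ValidationError):
            permutation_null(xy, 11, ClusterIndexConfig(k=2, B=5))

    def test_square_monte_carlo_matches_enumeration(self, square_xy):
        # exhaustive null over C(4,2)=6 labelings is {1,1,0,0,0,0}
        cfg = ClusterIndexConfig(k=1, window=500.0, B=6000, seed=7)
        scores, n_undef = permutation_null(square_xy, 2, cfg)
        assert n_undef == 0
        p_one = 2 / 6
        freq_one = np.mean(scores == 1.0)
        se = np.sqrt(p_one * (1 - p_one) / 6000)
        assert abs(freq_one - p_one) < 3 * se
        # only scores 0, 0.5 and 1 are possible with k=1 and 2 QCCs
        assert set(np.unique(scores)) <= {0.0, 0.5, 1.0}

    def test_hypergeometric_mean_dense_field(self, rng):
        # no discards: E[per-focal fraction] = (q-1)/(N-1)
        n, q = 200, 20
        xy = rng.uniform(0, 300, size=(n, 2))
        cfg = ClusterIndexConfig(k=10, window=5000.0, B=400, seed=3)
        scores, n_undef = permutation_null(xy, q, cfg)
        assert n_undef == 0
        expected = (q - 1) / (n - 1)
        se = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean() - expected) < 3 * se


class TestEmpiricalP:
    def test_observed_above_all_scores(self):
        assert empirical_p(1.0, np.zeros(1000)) == pytest.approx(1 / 1001)

    def test_observed_at_minimum(self):
        scores = np.array([0.2, 0.5, 0.9])
        assert empirical_p(0.2, scores) == 1.0

    def test_nan_scores_dropped(self):
        scores = np.array([0.1, np.nan, 0.3])
        assert empirical_p(0.5, scores) == pytest.approx(1 / 3)

    def test_no_defined_scores_errors(self):
        with pytest.raises(ValidationError):
            empirical_p(0.5, np.array([np.nan]))


class TestExactNull:
    def test_square_enumeration(self, square_xy):
        cfg = ClusterIndexConfig(k=1, window=500.0)
        scores, n_undef = exact_null(square_xy, 2, cfg)
        assert n_undef == 0
        assert sorted(scores.tolist()) == [0.0, 0.0, 0.0, 0.0, 1.0, 1.0]

    def test_full_labeling_single(self, square_xy):
        scores, _ = exact_null(square_xy, 4, ClusterIndexConfig(k=1, window=500.0))
        assert scores.tolist() == [1.0]

    def test_combinatorial_bound(self, rng):
        xy = rng.uniform(0, 100, size=(40, 2))
        with pytest.raises(ValidationError, match="Monte-Carlo"):
            exact_null(xy, 20, ClusterIndexConfig(k=2))

    def test_exact_p_of_square_observed(self, square_xy):
        cfg = ClusterIndexConfig(k=1, window=500.0)
        labels = np.array([True, True, False, False])
        observed = qcc_ci(square_xy, labels, cfg).qcc_ci
        assert observed == 1.0
        scores, _ = exact_null(square_xy, 2, cfg)
        exact_p = np.mean(scores >= observed)
        assert exact_p == pytest.approx(2 / 6)


class TestClusterIndexTest:
    def test_full_pipeline_fields(self, rng):
        n = 150
        xy = rng.uniform(0, 800, size=(n, 2))
        labels = rng.random(n) < 0.1
        labels[0] = True
        cfg = ClusterIndexConfig(k=10, window=500.0, B=99, seed=5)
        res = cluster_index_test(xy, labels, cfg)
        assert res.defined
        assert 0.0 <= res.qcc_ci <= 1.0
        assert res.permutation_scores.size + res.n_undefined_permutations == 99
        assert 0.0 < res.p_value <= 1.0
        assert res.seed == 5

    def test_tight_cluster_is_significant(self, rng):
        # 20 QCCs packed into a 10x10 box inside a 2000x2000 field
        n_bg = 400
        bg = rng.uniform(0, 2000, size=(n_bg, 2))
        cluster = rng.uniform(1000, 1010, size=(20, 2))
        xy = np.vstack([bg, cluster])
        labels = np.r_[np.zeros(n_bg, bool), np.ones(20, bool)]
        cfg = ClusterIndexConfig(k=10, window=500.0, B=200, seed=9)
        res = cluster_index_test(xy, labels, cfg)
        assert res.p_value <= 0.05

    def test_p_value_identity_with_empirical_p(self, rng):
        n = 100
        xy = rng.uniform(0, 500, size=(n, 2))
        labels = rng.random(n) < 0.2
        labels[0] = True
        cfg = ClusterIndexConfig(k=5, window=500.0, B=50, seed=2)
        res = cluster_index_test(xy, labels, cfg)
        assert res.p_value == empirical_p(res.qcc_ci, res.permutation_scores)


class TestNeighborIndex:
    def test_tie_break_by_cell_id(self):
        # two candidates equidistant from the focal: lower cell_id wins
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [5.0, 0.0]])
        ids = np.array([0, 7, 3, 9])
        cfg = ClusterIndexConfig(k=1, window=500.0)
        index = build_neighbor_index(xy, ids, cfg)
        assert ids[index.neighbors[0, 0]] == 3  # (1,0) and (-1,0) tie; id 3 < 7

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ClusterIndexConfig(k=0)
        with pytest.raises(ValidationError):
            ClusterIndexConfig(window=0)
        with pytest.raises(ValidationError):
            ClusterIndexConfig(B=0)
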