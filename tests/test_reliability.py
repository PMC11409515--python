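import itertools

import numpy as np
import pytest

from relmap import (
    GridSpec,
    NoisePool,
    ProbeType,
    ReliabilityMap,
    ValidationError,
    build_noise_pool,
    build_reliability_map,
    lookup_q,
    q_score,
    simulate_beta_distribution,
    unreliability_scores,
)

from conftest import make_dataset


def exhaustive_nearest(rmap, m, u):
    """Independent oracle: scan every grid node for the nearest one."""
    grid = rmap.grid
    cm, cu = m - rmap.m_noise_mean, u - rmap.u_noise_mean
    if cm > grid.max or cu > grid.max:
        return 0.0
    cm, cu = max(cm, grid.min), max(cu, grid.min)
    axis = grid.axis()
    best = None
    for k, l in itertools.product(range(len(axis)), repeat=2):
        d = (axis[k] - cm) ** 2 + (axis[l] - cu) ** 2
        if best is None or d < best[0]:  # strict: first (lower-index) wins ties
            best = (d, k, l)
    return rmap.q[best[1], best[2]]


@pytest.fixture(scope="module")
def pool():
    return NoisePool(
        type_channel=ProbeType.II,
        m_noise=np.array([10.0, 20.0, 35.0, 80.0]),
        u_noise=np.array([15.0, 30.0, 45.0, 100.0]),
    )


@pytest.fixture(scope="module")
def small_map(pool):
    return build_reliability_map(pool, GridSpec(0, 1000, 100), n_draws=400, seed=9)


class TestNoisePool:
    def test_type2_pools_green_into_m_and_red_into_u(self):
        ds = make_dataset(m=[[1.0, 1.0, 1.0]], u=[[1.0, 1.0, 1.0]],
                          noise_g=(10.0, 20.0), noise_r=(30.0, 50.0))
        pool = build_noise_pool(ds, ProbeType.II)
        assert pool.m_noise_mean == pytest.approx(15.0)
        assert pool.u_noise_mean == pytest.approx(40.0)

    def test_type1_green_draws_both_pools_from_green(self):
        ds = make_dataset(m=[[1.0, 1.0, 1.0]], u=[[1.0, 1.0, 1.0]],
                          noise_g=(10.0, 20.0), noise_r=(30.0, 50.0))
        pool = build_noise_pool(ds, ProbeType.I_GRN)
        np.testing.assert_array_equal(np.sort(pool.m_noise), [10.0, 20.0])
        np.testing.assert_array_equal(np.sort(pool.u_noise), [10.0, 20.0])

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError):
            NoisePool(type_channel=ProbeType.II, m_noise=np.array([]), u_noise=np.array([1.0]))


class TestSimulateBeta:
    def test_no_noise_gives_beta_one_at_pure_m_signal(self):
        zero = NoisePool(ProbeType.II, np.zeros(3), np.zeros(3))
        betas = simulate_beta_distribution(5000.0, 0.0, zero, n_draws=50, seed=0)
        np.testing.assert_array_equal(betas, 1.0)

    def test_symmetric_pool_at_origin_centres_on_half(self):
        # brute-force: with identical 2-value pools the 4 equally likely
        # (m_err, u_err) combos give betas {0.5, a/(a+b), b/(a+b), 0.5}
        # whose mean is exactly 0.5 by symmetry.
        a, b = 40.0, 160.0
        combos = [(x, y) for x in (a, b) for y in (a, b)]
        exact = np.mean([x / (x + y) for x, y in combos])
        assert exact == pytest.approx(0.5)
        sym = NoisePool(ProbeType.II, np.array([a, b]), np.array([a, b]))
        betas = simulate_beta_distribution(0.0, 0.0, sym, n_draws=40_000, seed=1)
        assert betas.mean() == pytest.approx(0.5, abs=0.01)

    def test_fixed_seed_reproducible(self, pool):
        b1 = simulate_beta_distribution(300.0, 200.0, pool, 100, seed=7)
        b2 = simulate_beta_distribution(300.0, 200.0, pool, 100, seed=7)
        np.testing.assert_array_equal(b1, b2)

    def test_values_within_unit_interval(self, pool):
        betas = simulate_beta_distribution(100.0, 100.0, pool, 1000, seed=3)
        assert betas.min() >= 0.0 and betas.max() <= 1.0

    def test_too_few_draws_rejected(self, pool):
        with pytest.raises(ValidationError):
            simulate_beta_distribution(0.0, 0.0, pool, n_draws=1, seed=0)


class TestQScore:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.5, 0.5, 0.5], 0.0),
            ([0.0, 1.0], 0.5),
            ([0.2, 0.4, 0.6], 2.0 / 15.0),
        ],
    )
    def test_hand_arithmetic(self, values, expected):
        assert q_score(np.array(values)) == pytest.approx(expected)

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            q_score(np.array([0.5]))


class TestReliabilityMap:
    def test_default_grid_has_51_axis_points(self, pool):
        rmap = build_reliability_map(pool, n_draws=10, seed=0)
        assert rmap.q.shape == (51, 51)

    def test_zero_noise_pool_gives_identically_zero_map(self):
        zero = NoisePool(ProbeType.II, np.zeros(5), np.zeros(5))
        rmap = build_reliability_map(zero, GridSpec(0, 500, 100), n_draws=20, seed=0)
        np.testing.assert_array_equal(rmap.q, 0.0)

    def test_q_bounded_by_half(self, small_map):
        assert small_map.q.min() >= 0.0
        assert small_map.q.max() <= 0.5

    def test_identical_seeds_give_bit_identical_maps(self, pool):
        g = GridSpec(0, 500, 100)
        m1 = build_reliability_map(pool, g, n_draws=50, seed=4)
        m2 = build_reliability_map(pool, g, n_draws=50, seed=4)
        np.testing.assert_array_equal(m1.q, m2.q)

    def test_identical_pools_give_nearly_symmetric_map(self):
        sym = NoisePool(ProbeType.I_GRN, np.array([20.0, 60.0, 150.0]), np.array([20.0, 60.0, 150.0]))
        rmap = build_reliability_map(sym, GridSpec(0, 500, 100), n_draws=4000, seed=2)
        assert np.abs(rmap.q - rmap.q.T).max() < 0.01  # resampling tolerance

    def test_diagonal_q_declines_with_intensity(self, pool):
        rmap = build_reliability_map(pool, n_draws=1000, seed=5)
        q = lambda m, u: lookup_q(rmap, m + rmap.m_noise_mean, u + rmap.u_noise_mean)
        assert q(100, 100) > q(4000, 4000)


class TestLookup:
    def test_above_grid_max_is_fully_reliable(self, small_map):
        m0 = small_map.m_noise_mean
        u0 = small_map.u_noise_mean
        assert lookup_q(small_map, 5100.0 + m0, 200.0 + u0) == 0.0

    def test_exact_node_hit(self, small_map):
        val = lookup_q(small_map, 300.0 + small_map.m_noise_mean, 200.0 + small_map.u_noise_mean)
        assert val == small_map.q[3, 2]

    def test_below_grid_clamps_to_minimum(self, small_map):
        got = lookup_q(small_map, small_map.m_noise_mean - 30.0, 250.0 + small_map.u_noise_mean)
        oracle = exhaustive_nearest(small_map, small_map.m_noise_mean - 30.0, 250.0 + small_map.u_noise_mean)
        assert got == oracle == small_map.q[0, 2] or got == oracle == small_map.q[0, 3]

    def test_matches_exhaustive_search_on_random_coordinates(self, small_map):
        rng = np.random.default_rng(12)
        for _ in range(120):
            m = rng.uniform(-100, 1300)
            u = rng.uniform(-100, 1300)
            assert lookup_q(small_map, m, u) == exhaustive_nearest(small_map, m, u)

    def test_halfway_tie_prefers_lower_index(self, small_map):
        m = 150.0 + small_map.m_noise_mean  # exactly between nodes 1 and 2
        u = 0.0 + small_map.u_noise_mean
        assert lookup_q(small_map, m, u) == small_map.q[1, 0]
        assert exhaustive_nearest(small_map, m, u) == small_map.q[1, 0]


class TestUnreliabilityScores:
    def _map_with_q(self, q):
        grid = GridSpec(0, 200, 100)
        return ReliabilityMap(
            grid=grid, q=np.asarray(q, dtype=float), type_channel=ProbeType.II,
            n_draws=10, seed=0, m_noise_mean=0.0, u_noise_mean=0.0,
        )

    def test_mean_of_per_sample_q_values(self):
        # two samples land on nodes with Q = 0.02 and 0.04 -> score 0.03
        q = np.zeros((3, 3))
        q[0, 0], q[1, 1] = 0.02, 0.04
        rmap = self._map_with_q(q)
        ds = make_dataset(m=[[0.0], [100.0]], u=[[0.0], [100.0]])
        table = unreliability_scores(ds, rmap, ProbeType.II)
        assert table["unreliability"].iloc[0] == pytest.approx(0.03)
        assert table["n_samples_used"].iloc[0] == 2

    def test_all_samples_above_grid_give_zero(self):
        rmap = self._map_with_q(np.full((3, 3), 0.1))
        ds = make_dataset(m=[[5000.0]], u=[[5000.0]])
        assert unreliability_scores(ds, rmap, ProbeType.II)["unreliability"].iloc[0] == 0.0

    def test_single_sample_score_is_that_samples_q(self):
        q = np.zeros((3, 3))
        q[1, 2] = 0.25
        rmap = self._map_with_q(q)
        ds = make_dataset(m=[[100.0]], u=[[200.0]])
        assert unreliability_scores(ds, rmap, ProbeType.II)["unreliability"].iloc[0] == 0.25

    def test_missing_samples_excluded(self):
        q = np.full((3, 3), 0.2)
        rmap = self._map_with_q(q)
        ds = make_dataset(m=[[100.0], [np.nan]], u=[[100.0], [np.nan]])
        table = unreliability_scores(ds, rmap, ProbeType.II)
        assert table["n_samples_used"].iloc[0] == 1
        assert table["unreliability"].iloc[0] == pytest.approx(0.2)
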