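"""Microstate MSM: counts, connectivity, reversible MLE, ITS, CK, FES."""

import numpy as np
import pytest

import loopmsm as lm
from loopmsm.msm import (
    ck_test,
    cluster_microstates,
    count_matrix,
    estimate_reversible_msm,
    free_energy_surface,
    implied_timescales,
    largest_connected_set,
)


class TestClustering:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 0.1, size=(500, 2))
        b = rng.normal([10, 10], 0.1, size=(500, 2))
        X = np.vstack([a, b])
        dtr = cluster_microstates(X, k=2, seed=1)
        lab = dtr.dtrajs[0]
        purity = max(np.mean(lab[:500] == lab[0]), np.mean(lab[:500] != lab[0]))
        assert purity >= 0.99

    def test_k1_all_zero(self):
        dtr = cluster_microstates(np.random.default_rng(1).normal(size=(50, 2)), 1)
        assert np.all(dtr.dtrajs[0] == 0)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(2).normal(size=(300, 2))
        a = cluster_microstates(X, 5, seed=7)
        b = cluster_microstates(X, 5, seed=7)
        assert np.allclose(a.centers, b.centers)

    def test_k_exceeds_frames(self):
        with pytest.raises(ValueError):
            cluster_microstates(np.zeros((3, 2)), 10)


class TestCounts:
    def test_hand_counted(self):
        C = count_matrix([np.array([0, 1, 0, 1])], 1, n_states=2)
        assert np.array_equal(C, [[0.0, 2.0], [1.0, 0.0]])

    def test_constant_sequence(self):
        C = count_matrix([np.zeros(10, dtype=int)], 1, n_states=1)
        assert C[0, 0] == 9

    def test_trajectories_add(self):
        d = [np.array([0, 1, 0, 1]), np.array([0, 1, 0, 1])]
        assert np.array_equal(count_matrix(d, 1, 2), 2 * count_matrix(d[:1], 1, 2))

    def test_lag_too_long(self):
        with pytest.raises(ValueError):
            count_matrix([np.array([0, 1])], 5)


class TestConnectivity:
    def test_dominant_block(self):
        C = np.array([[50.0, 50.0, 0.0], [50.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert np.array_equal(largest_connected_set(C), [0, 1])

    def test_fully_connected(self):
        C = np.ones((4, 4))
        assert np.array_equal(largest_connected_set(C), range(4))

    def test_one_way_chain_singletons(self):
        C = np.array([[0.0, 5.0, 0.0], [0.0, 0.0, 5.0], [0.0, 0.0, 1.0]])
        # strong connectivity: no cycles except the self-looping state
        assert len(largest_connected_set(C)) == 1


class TestReversibleMLE:
    def test_symmetric_counts_closed_form(self):
        C = np.array([[90.0, 10.0], [10.0, 90.0]])
        m = estimate_reversible_msm(C, lag=1)
        assert np.allclose(m.T, [[0.9, 0.1], [0.1, 0.9]], atol=1e-9)
        assert np.allclose(m.pi, [0.5, 0.5], atol=1e-9)

    def test_matches_grid_likelihood_maximizer(self):
        """2-state reversible MLE vs brute-force likelihood grid search.

        Any 2-state chain satisfies detailed balance, so the reversible MLE
        coincides with the unconstrained maximizer over (T01, T10).
        """
        rng = np.random.default_rng(3)
        grid = np.linspace(1e-3, 1 - 1e-3, 999)
        for _ in range(100):
            C = rng.integers(1, 200, size=(2, 2)).astype(float)
            m = estimate_reversible_msm(C, lag=1)
            # profile likelihood: rows are independent given no constraint
            ll01 = C[0, 0] * np.log(1 - grid) + C[0, 1] * np.log(grid)
            ll10 = C[1, 1] * np.log(1 - grid) + C[1, 0] * np.log(grid)
            assert m.T[0, 1] == pytest.approx(grid[np.argmax(ll01)], abs=2e-3)
            assert m.T[1, 0] == pytest.approx(grid[np.argmax(ll10)], abs=2e-3)

    def test_stationary_distribution_recovered_from_simulation(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        _, paths, _ = lm.gen_hidden_markov_features(
            T, np.array([[0.0], [1.0]]), 0.0, 1, 100_000, seed=4
        )
        C = count_matrix(paths, 1, 2)
        m = estimate_reversible_msm(C, lag=1)
        n = len(paths[0])
        se = np.sqrt(2.0 / 9.0 / 0.3 / n)  # occupancy SE with autocorrelation
        assert m.pi[0] == pytest.approx(2.0 / 3.0, abs=3 * se)

    def test_detailed_balance_residual(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            C = rng.integers(1, 50, size=(4, 4)).astype(float)
            m = estimate_reversible_msm(C, lag=1)
            flux = m.pi[:, None] * m.T
            assert np.abs(flux - flux.T).max() < 1e-8

    def test_timescales_invariant_under_relabeling(self):
        rng = np.random.default_rng(6)
        C = rng.integers(1, 50, size=(5, 5)).astype(float)
        m = estimate_reversible_msm(C, lag=2)
        perm = rng.permutation(5)
        m2 = estimate_reversible_msm(C[np.ix_(perm, perm)], lag=2)
        assert np.allclose(np.sort(m.timescales(4)), np.sort(m2.timescales(4)),
                           rtol=1e-8)


@pytest.fixture(scope="module")
def markov_dtrajs():
    T = np.array([[0.95, 0.04, 0.01],
                  [0.08, 0.90, 0.02],
                  [0.02, 0.04, 0.94]])
    _, paths, _ = lm.gen_hidden_markov_features(
        T, np.eye(3), 0.0, 4, 50_000, seed=7
    )
    return paths


class TestImpliedTimescalesAndCK:
    def test_flat_in_lag_for_markovian_data(self, markov_dtrajs):
        its = implied_timescales(markov_dtrajs, lags=[1, 2, 5, 10], n_its=2)
        t1 = its["t1"].to_numpy()
        assert np.all(np.abs(t1[1:] - t1[0]) / t1[0] < 0.15)

    def test_white_noise_short_timescales(self):
        rng = np.random.default_rng(8)
        d = [rng.integers(0, 3, size=20_000)]
        its = implied_timescales(d, lags=[1], n_its=2)
        assert its["t1"].iloc[0] < 1.0

    def test_single_lag_single_row(self, markov_dtrajs):
        its = implied_timescales(markov_dtrajs, lags=[1], n_its=3)
        assert len(its) == 1

    def test_ck_factor_one_exact(self, markov_dtrajs):
        C = count_matrix(markov_dtrajs, 1, 3)
        m = estimate_reversible_msm(C, lag=1)
        res = ck_test(m, markov_dtrajs, [[0], [1], [2]], factors=[1])
        assert res["deviation"].max() < 1e-12

    def test_ck_markovian_small_deviation(self, markov_dtrajs):
        C = count_matrix(markov_dtrajs, 1, 3)
        m = estimate_reversible_msm(C, lag=1)
        res = ck_test(m, markov_dtrajs, [[0], [1], [2]], factors=[2, 5])
        assert res["deviation"].max() < 0.02

    def test_ck_flags_non_markovian(self):
        # deterministic dwell of 10 frames per state: at lag 5 the chain
        # looks half-mixed, but at lag 10 it is always in the opposite
        # state -- T(5)^2 cannot predict that
        rng = np.random.default_rng(9)
        n = 20_000
        d = (np.arange(n) // 10) % 2
        flip = rng.random(n) < 0.01
        d = np.where(flip, 1 - d, d)
        C = count_matrix([d], 5, 2)
        m = estimate_reversible_msm(C, lag=5)
        res = ck_test(m, [d], [[0], [1]], factors=[2])
        assert res["deviation"].max() > 0.2


class TestFreeEnergySurface:
    def test_uniform_flat(self):
        # multinomial fluctuations: with mean bin count m the F range is
        # ~2*3/sqrt(m); 1e5 frames over 100 bins gives m=1000, range ~0.19
        rng = np.random.default_rng(10)
        fes = free_energy_surface(rng.random((100_000, 2)), bins=10)
        assert np.nanmax(fes.F) < 0.3

    def test_two_cluster_depth_ratio(self):
        # identical cluster shapes, populations 2:1 -> basin-minimum
        # free-energy difference ln 2; sd >> bin width so bin alignment
        # cannot distort the peak densities
        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.3, size=(40_000, 2))
        b = rng.normal(3, 0.3, size=(20_000, 2))
        fes = free_energy_surface(np.vstack([a, b]), bins=30)
        q = fes.F.copy()
        half = len(fes.x_edges) // 2
        f_a = np.nanmin(q[:half, :half])
        f_b = np.nanmin(q[half:, half:])
        assert (f_b - f_a) == pytest.approx(np.log(2.0), abs=0.1)

    def test_min_zero_and_mask(self):
        rng = np.random.default_rng(12)
        fes = free_energy_surface(rng.normal(size=(5000, 2)), bins=20)
        assert fes.minimum == 0.0
        assert np.isnan(fes.F[fes.mask]).all()

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(5000, 2))
        f1 = free_energy_surface(X, bins=15)
        f2 = free_energy_surface(X, bins=15, weights=np.full(5000, 2.0))
        assert np.allclose(np.nan_to_num(f1.F), np.nan_to_num(f2.F))

    def test_degenerate_single_bin(self):
        with pytest.raises(ValueError, match="bin"):
            free_energy_surface(np.zeros((100, 2)), bins=10)
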