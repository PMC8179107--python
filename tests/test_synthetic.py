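"""Generator ground truth: hidden chains, planted geometry, exact MFPTs."""

import numpy as np
import pytest

import loopmsm as lm
from loopmsm.synthetic import stationary_distribution

T_2STATE = np.array([[0.9, 0.1], [0.2, 0.8]])


class TestHiddenMarkovFeatures:
    def test_identity_chain_path_is_constant(self):
        fm, paths, _ = lm.gen_hidden_markov_features(
            np.array([[1.0, 0.0], [0.0, 1.0]]),
            np.array([[0.0], [5.0]]),
            noise_sd=0.1, n_traj=1, n_frames=100, seed=0,
        )
        # absorbing identity chain never leaves its initial state
        assert len(np.unique(paths[0])) == 1

    def test_reducible_chain_rejected(self):
        T = np.array([[1.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.0, 0.5, 0.5]])
        with pytest.raises(ValueError, match="reducible"):
            lm.gen_hidden_markov_features(
                T, np.array([[0.0], [5.0], [9.0]]), 0.1, 1, 10, seed=0
            )

    def test_nonstochastic_rejected(self):
        with pytest.raises(ValueError):
            lm.gen_hidden_markov_features(
                np.array([[0.5, 0.4], [0.2, 0.8]]),
                np.array([[0.0], [5.0]]), 0.1, 1, 10, 0,
            )

    def test_stationary_frequency_recovered(self):
        # pi solves piT=pi for T=[[.9,.1],[.2,.8]]: pi = (2/3, 1/3)
        n = 200_000
        _, paths, kin = lm.gen_hidden_markov_features(
            T_2STATE, np.array([[0.0], [5.0]]), 0.1, 1, n, seed=42
        )
        freq0 = np.mean(paths[0] == 0)
        # autocorrelation time of the chain ~ 1/(1-lambda2) = 1/0.3
        se = np.sqrt(2.0 / 9.0 / 0.3 / n)
        assert abs(freq0 - 2.0 / 3.0) < 3 * se
        assert np.allclose(kin.pi_true, [2.0 / 3.0, 1.0 / 3.0])

    def test_zero_noise_emits_exact_centroids(self):
        means = np.array([[0.0, 1.0], [5.0, -2.0]])
        fm, paths, _ = lm.gen_hidden_markov_features(
            T_2STATE, means, 0.0, 1, 500, seed=1
        )
        assert np.array_equal(fm.values, means[paths[0]])

    def test_empirical_transition_counts_match_T(self):
        _, paths, _ = lm.gen_hidden_markov_features(
            T_2STATE, np.array([[0.0], [5.0]]), 0.1, 1, 100_000, seed=2
        )
        p = paths[0]
        C = np.zeros((2, 2))
        np.add.at(C, (p[:-1], p[1:]), 1.0)
        T_emp = C / C.sum(axis=1, keepdims=True)
        rowc = C.sum(axis=1)
        for i in range(2):
            assert np.abs(T_emp[i] - T_2STATE[i]).max() < 5.0 / np.sqrt(rowc[i])

    def test_bit_reproducible(self):
        a = lm.gen_hidden_markov_features(T_2STATE, np.array([[0.0], [5.0]]),
                                          0.3, 2, 500, seed=9)
        b = lm.gen_hidden_markov_features(T_2STATE, np.array([[0.0], [5.0]]),
                                          0.3, 2, 500, seed=9)
        assert np.array_equal(a[0].values, b[0].values)
        assert all(np.array_equal(x, y) for x, y in zip(a[1], b[1]))


class TestTrueMFPT:
    def test_two_state_closed_form(self):
        T = np.array([[0.9, 0.1], [0.3, 0.7]])
        assert lm.true_mfpt(T, [0], [1]) == pytest.approx(10.0, abs=1e-9)
        assert lm.true_mfpt(T, [1], [0]) == pytest.approx(1 / 0.3, abs=1e-9)

    def test_target_everything_is_zero(self):
        T = np.array([[0.9, 0.1], [0.3, 0.7]])
        assert lm.true_mfpt(T, [0], [0, 1]) == 0.0

    def test_ring_matches_path_enumeration(self):
        # 3-state ring, hop left/right with prob 1/2
        T = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
        # brute-force: m = sum_k k * P(first hit at step k), enumerated exactly
        # via the sub-stochastic propagation restricted to non-target states
        target = 2
        Q = T[:2, :2]
        h = T[:2, target]
        p = np.eye(2)
        m_enum = 0.0
        for k in range(1, 10_000):
            m_enum_step = (p @ h) * k
            m_enum += m_enum_step
            p = p @ Q
        assert lm.true_mfpt(T, [0], [2]) == pytest.approx(m_enum[0], abs=1e-9)

    def test_matches_first_passage_simulation(self):
        rng = np.random.default_rng(5)
        T = np.array([
            [0.80, 0.15, 0.05],
            [0.10, 0.85, 0.05],
            [0.05, 0.15, 0.80],
        ])
        n_rep = 100_000
        state = np.zeros(n_rep, dtype=int)
        steps = np.zeros(n_rep)
        alive = np.ones(n_rep, dtype=bool)
        cum = np.cumsum(T, axis=1)
        for step in range(1, 5000):
            if not alive.any():
                break
            u = rng.random(alive.sum())
            state[alive] = np.array(
                [np.searchsorted(cum[s], x) for s, x in zip(state[alive], u)]
            )
            hit = alive & (state == 2)
            steps[hit] = step
            alive &= state != 2
        sim = steps.mean()
        se = steps.std(ddof=1) / np.sqrt(n_rep)
        assert lm.true_mfpt(T, [0], [2]) == pytest.approx(sim, abs=3 * se)

    def test_unreachable_target_named(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="unreachable"):
            lm.true_mfpt(T, [0], [1])


class TestToyLoopGenerator:
    def test_zero_rates_static_structure(self):
        syn = lm.gen_toy_loop_trajectory(
            loop_defs=(lm.LoopBlock(8, 12, 0.0), lm.LoopBlock(28, 33, 0.0)),
            jitter_sd=0.2, n_traj=2, n_frames=400, seed=0,
        )
        rmsf = lm.ca_rmsf(syn.ensemble)
        # all residues jitter-only: RMSF ~ sigma*sqrt(3) everywhere
        assert np.all(rmsf < 0.2 * np.sqrt(3) * 1.3)
        assert np.all(rmsf > 0.2 * np.sqrt(3) * 0.7)

    def test_product_stationary_uniform(self, toy):
        assert np.allclose(toy.kinetics.pi_true, 0.25, atol=1e-10)

    def test_true_mfpt_slow_block_closed_form(self):
        p = 0.001
        syn = lm.gen_toy_loop_trajectory(
            loop_defs=(lm.LoopBlock(8, 12, 0.02), lm.LoopBlock(28, 33, p)),
            n_traj=1, n_frames=10, seed=0,
        )
        # marginal slow-block MFPT: source = states with slow conf 0,
        # target = states with slow conf 1 -> exactly 1/p
        T = syn.kinetics.T_true
        assert lm.true_mfpt(T, [0, 2], [1, 3]) == pytest.approx(1 / p, rel=1e-9)

    def test_hidden_path_lengths_and_frequencies(self, toy):
        for xyz, h in zip(toy.ensemble.trajectories, toy.hidden_path):
            assert xyz.shape[0] == len(h)
        freq = np.bincount(np.concatenate(toy.hidden_path), minlength=4)
        freq = freq / freq.sum()
        assert np.abs(freq - 0.25).max() < 0.12  # loose: slow process, few flips

    def test_kinetics_invariants(self, toy):
        kin = toy.kinetics
        assert np.allclose(kin.T_true.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(kin.pi_true @ kin.T_true, kin.pi_true, atol=1e-10)
        assert np.allclose(np.diag(kin.mfpt_true), 0.0)
        assert not set(kin.slow_loop_residues) & set(kin.fast_loop_residues)

    def test_separability_warning_for_tiny_displacement(self):
        syn = lm.gen_toy_loop_trajectory(
            loop_defs=(
                lm.LoopBlock(8, 12, 0.01, displacement=0.1),
                lm.LoopBlock(28, 33, 0.002),
            ),
            jitter_sd=0.3, n_traj=1, n_frames=50, seed=0,
        )
        assert syn.separability_warning

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            lm.gen_toy_loop_trajectory(
                loop_defs=(lm.LoopBlock(8, 12, 0.01), lm.LoopBlock(12, 15, 0.1)),
                n_traj=1, n_frames=10,
            )

    def test_bit_reproducible(self):
        a = lm.gen_toy_loop_trajectory(n_traj=1, n_frames=200, seed=17)
        b = lm.gen_toy_loop_trajectory(n_traj=1, n_frames=200, seed=17)
        assert np.array_equal(a.ensemble.trajectories[0], b.ensemble.trajectories[0])


def test_stationary_distribution_solves_fixed_point():
    rng = np.random.default_rng(0)
    T = rng.random((4, 4)) + 0.1
    T /= T.sum(axis=1, keepdims=True)
    pi = stationary_distribution(T)
    assert np.allclose(pi @ T, pi, atol=1e-10)
    assert pi.sum() == pytest.approx(1.0)


class TestRelaxationGenerator:
    def test_rigid_zero_noise_noe_constant(self):
        truth = lm.RelaxationTruth(
            S2_true=np.ones(10), tau_e_true=np.zeros(10), tau_m_true=10.0
        )
        ds = lm.gen_relaxation_data(truth, seed=0)
        assert np.ptp(ds.NOE) < 1e-12
        assert np.ptp(ds.R2 / ds.R1) < 1e-12

    def test_same_seed_identical(self):
        truth = lm.RelaxationTruth(
            S2_true=np.full(8, 0.8), tau_e_true=np.full(8, 50.0),
            tau_m_true=14.7,
            noise_sd={"R1": 0.02, "R2": 0.3, "NOE": 0.02},
        )
        a = lm.gen_relaxation_data(truth, seed=3)
        b = lm.gen_relaxation_data(truth, seed=3)
        assert np.array_equal(a.R1, b.R1) and np.array_equal(a.NOE, b.NOE)

    def test_truth_validation(self):
        with pytest.raises(ValueError):
            lm.RelaxationTruth(S2_true=np.array([1.2]), tau_e_true=np.array([10.0]),
                               tau_m_true=10.0)
        with pytest.raises(ValueError):
            lm.RelaxationTruth(S2_true=np.array([0.8]), tau_e_true=np.array([10.0]),
                               tau_m_true=-1.0)
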