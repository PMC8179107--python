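"""Featurization: pair enumeration, distances, pruning rules, RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import loopmsm as lm
from loopmsm.featurize import (
    FeatureDefinition,
    FeatureMatrix,
    Topology,
    TrajectoryEnsemble,
    _superpose,
)


def _topo(n, clip=0):
    return Topology(tuple((i + 1, "ALA", "A") for i in range(n)), terminal_clip=clip)


class TestEnumerate:
    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 10), (20, 190)])
    def test_counts(self, n, expected):
        assert len(lm.enumerate_ca_pairs(_topo(n))) == expected

    def test_terminal_clip_excluded(self):
        defs = lm.enumerate_ca_pairs(_topo(10, clip=2))
        used = {d.residue_i for d in defs} | {d.residue_j for d in defs}
        assert used == set(range(3, 9))
        assert len(defs) == 6 * 5 // 2

    @given(st.integers(min_value=2, max_value=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_count_formula(self, n):
        assert len(lm.enumerate_ca_pairs(_topo(n))) == n * (n - 1) // 2

    def test_too_few_residues(self):
        with pytest.raises(ValueError):
            lm.enumerate_ca_pairs(_topo(5, clip=2))

    def test_lexicographic_order(self):
        defs = lm.enumerate_ca_pairs(_topo(4))
        assert [d.label for d in defs] == [
            "D_1_2", "D_1_3", "D_1_4", "D_2_3", "D_2_4", "D_3_4"
        ]


class TestComputeFeatures:
    def test_fixed_pair_constant_distance(self):
        xyz = np.zeros((5, 2, 3))
        xyz[:, 1, 0] = 5.0
        ens = TrajectoryEnsemble([xyz], _topo(2))
        fm = lm.compute_features(ens, [FeatureDefinition(1, 2)])
        assert np.allclose(fm.values, 5.0)

    def test_degenerate_origin(self):
        ens = TrajectoryEnsemble([np.zeros((3, 4, 3))], _topo(4))
        fm = lm.compute_features(ens, lm.enumerate_ca_pairs(_topo(4)))
        assert np.allclose(fm.values, 0.0)

    def test_matches_scalar_arithmetic(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(size=(7, 6, 3))
        ens = TrajectoryEnsemble([xyz], _topo(6))
        defs = lm.enumerate_ca_pairs(_topo(6))
        fm = lm.compute_features(ens, defs)
        f, k = 3, 8  # arbitrary frame and feature
        d = defs[k]
        a, b = xyz[f, d.residue_i - 1], xyz[f, d.residue_j - 1]
        manual = np.sqrt(sum((a[c] - b[c]) ** 2 for c in range(3)))
        assert fm.values[f, k] == pytest.approx(manual, abs=1e-12)

    def test_out_of_range_residue(self):
        ens = TrajectoryEnsemble([np.zeros((3, 4, 3))], _topo(4))
        with pytest.raises(ValueError, match="residue"):
            lm.compute_features(ens, [FeatureDefinition(1, 9)])

    def test_segments_recorded(self):
        ens = TrajectoryEnsemble(
            [np.zeros((3, 2, 3)), np.zeros((5, 2, 3))], _topo(2)
        )
        fm = lm.compute_features(ens, [FeatureDefinition(1, 2)])
        assert fm.segment_lengths == [3, 5]


class TestPrune:
    def _fm(self, cols):
        vals = np.column_stack(cols)
        defs = [FeatureDefinition(1, j + 2) for j in range(vals.shape[1])]
        return FeatureMatrix(vals, defs, [vals.shape[0]])

    def test_rules(self):
        n = 50
        close = np.full(n, 2.5)
        far = np.full(n, 12.0)
        mid = 6.0 + 2.0 * np.sin(np.arange(n))          # oscillates 4-8
        span = np.linspace(2.0, 12.0, n)                 # spans both bounds
        fm = self._fm([close, far, mid, span])
        kept, rep = lm.prune_features(fm)
        assert rep.removed_too_close == ["D_1_2"]
        assert rep.removed_too_far == ["D_1_3"]
        assert kept.labels == ["D_1_4", "D_1_5"]
        # brute-force scan of the rule semantics over every column
        for k, col in enumerate(fm.values.T):
            removed = all(v < 3 for v in col) or all(v > 10 for v in col)
            assert (fm.labels[k] not in kept.labels) == removed

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        fm = self._fm(list(2 + 10 * rng.random((6, 40))))
        once, _ = lm.prune_features(fm)
        twice, rep2 = lm.prune_features(once)
        assert twice.labels == once.labels and rep2.n_removed == 0

    def test_commutes_with_permutation(self):
        rng = np.random.default_rng(2)
        fm = self._fm(list(2 + 10 * rng.random((6, 40))))
        perm = rng.permutation(fm.n_features)
        fm_p = fm.subset([fm.labels[k] for k in perm])
        kept, _ = lm.prune_features(fm)
        kept_p, _ = lm.prune_features(fm_p)
        assert set(kept.labels) == set(kept_p.labels)

    def test_all_removed_raises(self):
        fm = self._fm([np.full(5, 1.0), np.full(5, 20.0)])
        with pytest.raises(ValueError, match="threshold"):
            lm.prune_features(fm)


class TestRMSF:
    def test_static_zero(self):
        xyz = np.tile(np.arange(12.0).reshape(4, 3), (5, 1, 1))
        assert np.allclose(lm.ca_rmsf(TrajectoryEnsemble([xyz], _topo(4))), 0.0)

    def test_alternating_axis_closed_form(self):
        # one residue oscillating +-a along x about its mean, others fixed:
        # deviation formula gives exactly a for it, 0 for the rest
        base = np.array([[0.0, 0, 0], [50, 0, 0], [0, 50, 0], [-50, -50, 0]])
        a = 0.05
        xyz = np.tile(base, (40, 1, 1))
        xyz[::2, 0, 0] += a
        xyz[1::2, 0, 0] -= a
        rmsf = lm.ca_rmsf(TrajectoryEnsemble([xyz], _topo(4)), superpose=False)
        assert rmsf[0] == pytest.approx(a, abs=1e-12)
        assert np.allclose(rmsf[1:], 0.0)

    def test_rotation_translation_invariant(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(size=(20, 6, 3)) * 0.3 + np.arange(6)[None, :, None] * 3.8
        ens = TrajectoryEnsemble([xyz.copy()], _topo(6))
        from scipy.spatial.transform import Rotation
        moved = np.empty_like(xyz)
        for f in range(xyz.shape[0]):
            R = Rotation.random(random_state=int(rng.integers(1 << 30)))
            moved[f] = R.apply(xyz[f]) + rng.normal(size=3) * 10
        rmsf_a = lm.ca_rmsf(ens)
        rmsf_b = lm.ca_rmsf(TrajectoryEnsemble([moved], _topo(6)))
        assert np.allclose(rmsf_a, rmsf_b, atol=1e-8)

    def test_jitter_level_gaussian(self):
        sigma = 0.25
        syn = lm.gen_toy_loop_trajectory(
            loop_defs=(lm.LoopBlock(8, 12, 0.0), lm.LoopBlock(28, 33, 0.0)),
            jitter_sd=sigma, n_traj=2, n_frames=3000, seed=4,
        )
        rmsf = lm.ca_rmsf(syn.ensemble)
        # E|x|^2 = 3 sigma^2 for isotropic jitter (superposition absorbs a
        # little variance, hence the 5% one-sided slack)
        assert np.allclose(rmsf.mean(), sigma * np.sqrt(3), rtol=0.05)

    def test_single_frame_error(self):
        with pytest.raises(ValueError):
            TrajectoryEnsemble([np.zeros((1, 3, 3))], _topo(3))


class TestIO:
    def test_pdb_dcd_round_trip(self, tmp_path):
        syn = lm.gen_toy_loop_trajectory(n_traj=2, n_frames=50, seed=9)
        from loopmsm.synthetic import write_ensemble
        paths = write_ensemble(syn, tmp_path)
        topo = lm.load_topology(paths["pdb"])
        assert topo.n_residues == 40
        ens = lm.load_trajectories(paths["dcd"], paths["pdb"], topology=topo)
        assert len(ens.trajectories) == 2
        assert np.allclose(
            ens.trajectories[0], syn.ensemble.trajectories[0], atol=1e-3
        )

    def test_stride(self, tmp_path):
        syn = lm.gen_toy_loop_trajectory(n_traj=1, n_frames=51, seed=9)
        from loopmsm.synthetic import write_ensemble
        paths = write_ensemble(syn, tmp_path)
        ens = lm.load_trajectories(paths["dcd"], paths["pdb"], stride=2, dt_ns=1.0)
        assert ens.trajectories[0].shape[0] == 26  # ceil(51/2)
        assert ens.dt_ns == 2.0

    def test_empty_path_list(self, tmp_path):
        with pytest.raises(ValueError):
            lm.load_trajectories([], tmp_path / "x.pdb")

    def test_feature_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        fm = FeatureMatrix(
            rng.random((10, 3)) * 8 + 2,
            [FeatureDefinition(1, 2), FeatureDefinition(1, 3), FeatureDefinition(2, 3)],
            [6, 4],
        )
        fm.to_csv(tmp_path / "f.csv", tmp_path / "f.json")
        back = FeatureMatrix.from_csv(tmp_path / "f.csv", tmp_path / "f.json")
        assert back.labels == fm.labels
        assert back.segment_lengths == [6, 4]
        assert np.allclose(back.values, fm.values, atol=1e-6)


def test_superpose_removes_rigid_motion():
    rng = np.random.default_rng(6)
    ref = rng.normal(size=(5, 3))
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_euler("xyz", [0.3, -0.2, 0.5])
    moved = rot.apply(ref) + np.array([1.0, -2.0, 3.0])
    out = _superpose(moved[None], ref)
    assert np.allclose(out[0], ref - ref.mean(axis=0), atol=1e-10)
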