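"""Synthetic trajectory and relaxation-data generators with known ground truth.

Every downstream stage (featurization, tICA, feature selection, MSM, HMM
coarse-graining, model-free fitting) is exercised against data produced
here, where the hidden kinetics, stationary distribution, mean first
passage times and relaxation parameters are known exactly.

The toy molecule is a 3-D bead chain (one bead per residue, 3.8 Å Cα
spacing along a gentle helix).  Two disjoint residue blocks play the role
of mobile loops: each block jumps between a small number of discrete
conformations under an independent discrete-time Markov chain, one block
switching markedly slower than the other.  All other ("scaffold")
residues only jitter about fixed positions.  The product of the block
chains is the planted macrostate process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .featurize import (
    FeatureDefinition,
    FeatureMatrix,
    Topology,
    TrajectoryEnsemble,
)

__all__ = [
    "PlantedKinetics",
    "SyntheticEnsemble",
    "RelaxationTruth",
    "LoopBlock",
    "stationary_distribution",
    "true_mfpt",
    "gen_hidden_markov_features",
    "gen_toy_loop_trajectory",
    "gen_relaxation_data",
    "write_ensemble",
]


# ---------------------------------------------------------------------------
# chain utilities

def _check_stochastic(T: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if (T < -tol).any():
        raise ValueError("transition matrix has negative entries")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    return T


def _check_irreducible(T: np.ndarray) -> None:
    n, _ = connected_components(T > 0, directed=True, connection="strong")
    if n != 1:
        raise ValueError("transition matrix is reducible (not irreducible)")


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution π with πT = π, by eigen-decomposition."""
    T = _check_stochastic(T)
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def true_mfpt(
    T: np.ndarray,
    source_set: Sequence[int],
    target_set: Sequence[int],
) -> float:
    """Exact mean first passage time (frames) from source set to target set.

    Solves m_i = 1 + Σ_{j∉target} T_ij m_j with m_i = 0 on the target, then
    returns the π-weighted average of m over the source states.
    """
    T = _check_stochastic(T)
    n = T.shape[0]
    source = sorted(set(int(s) for s in source_set))
    target = sorted(set(int(t) for t in target_set))
    if not target:
        raise ValueError("target set must be nonempty")
    if set(target) == set(range(n)):
        return 0.0
    if not source:
        raise ValueError("source set must be nonempty")
    if set(source) & set(target):
        raise ValueError("source and target sets must be disjoint")
    nontarget = [i for i in range(n) if i not in target]
    Q = T[np.ix_(nontarget, nontarget)]
    A = np.eye(len(nontarget)) - Q
    try:
        m = np.linalg.solve(A, np.ones(len(nontarget)))
    except np.linalg.LinAlgError:
        bad = _unreachable_states(T, target)
        raise ValueError(f"target unreachable from states {bad}") from None
    if not np.all(np.isfinite(m)) or (m < 0).any():
        bad = _unreachable_states(T, target)
        raise ValueError(f"target unreachable from states {bad}")
    full = np.zeros(n)
    full[nontarget] = m
    pi = stationary_distribution(T)
    w = pi[source] / pi[source].sum()
    return float(w @ full[source])


def _unreachable_states(T: np.ndarray, target: Sequence[int]) -> list[int]:
    """States from which no path reaches the target set."""
    n = T.shape[0]
    reach = set(target)
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if i not in reach and any(T[i, j] > 0 for j in reach):
                reach.add(i)
                changed = True
    return sorted(set(range(n)) - reach)


# ---------------------------------------------------------------------------
# ground-truth containers

@dataclass
class PlantedKinetics:
    """Exact hidden kinetics planted in a synthetic ensemble."""

    macrostates: list[str]
    T_true: np.ndarray            # row-stochastic, per frame interval
    pi_true: np.ndarray
    mfpt_true: np.ndarray         # frames; diagonal 0
    slow_loop_residues: tuple[int, ...] = ()
    fast_loop_residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.T_true = _check_stochastic(self.T_true)
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        if not np.allclose(self.pi_true @ self.T_true, self.pi_true, atol=1e-10):
            raise ValueError("pi_true is not stationary for T_true")
        self.mfpt_true = np.asarray(self.mfpt_true, dtype=float)
        if not np.allclose(np.diag(self.mfpt_true), 0.0):
            raise ValueError("MFPT diagonal must be 0")
        if set(self.slow_loop_residues) & set(self.fast_loop_residues):
            raise ValueError("slow and fast loop residue sets must be disjoint")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "macrostates": self.macrostates,
                    "T_true": self.T_true.tolist(),
                    "pi_true": self.pi_true.tolist(),
                    "mfpt_true": self.mfpt_true.tolist(),
                    "slow_loop_residues": list(self.slow_loop_residues),
                    "fast_loop_residues": list(self.fast_loop_residues),
                },
                indent=1,
            )
        )


@dataclass
class SyntheticEnsemble:
    """A generated ensemble together with its hidden path and kinetics."""

    ensemble: TrajectoryEnsemble
    hidden_path: list[np.ndarray]     # per trajectory, per frame macrostate id
    kinetics: PlantedKinetics
    seed: int
    separability_warning: bool = False

    def __post_init__(self) -> None:
        for xyz, h in zip(self.ensemble.trajectories, self.hidden_path):
            if xyz.shape[0] != len(h):
                raise ValueError("hidden path length != frame count")


@dataclass
class RelaxationTruth:
    """True model-free parameters behind a synthetic relaxation dataset."""

    S2_true: np.ndarray               # dimensionless, in [0, 1]
    tau_e_true: np.ndarray            # ps
    tau_m_true: float                 # ns, global
    field_MHz: float = 800.0
    noise_sd: dict = field(
        default_factory=lambda: {"R1": 0.0, "R2": 0.0, "NOE": 0.0}
    )
    rex_true: np.ndarray | None = None  # s^-1, optional exchange terms

    def __post_init__(self) -> None:
        self.S2_true = np.asarray(self.S2_true, dtype=float)
        self.tau_e_true = np.asarray(self.tau_e_true, dtype=float)
        if ((self.S2_true < 0) | (self.S2_true > 1)).any():
            raise ValueError("S2_true must lie in [0, 1]")
        if self.tau_m_true <= 0 or self.field_MHz <= 0:
            raise ValueError("tau_m_true and field_MHz must be positive")
        if (self.tau_e_true >= self.tau_m_true * 1e3).any():
            raise ValueError("tau_e_true (ps) must be < tau_m_true (ns)")
        if self.rex_true is None:
            self.rex_true = np.zeros_like(self.S2_true)


# ---------------------------------------------------------------------------
# hidden-chain simulation

def _simulate_chain(
    T: np.ndarray, n_frames: int, rng: np.random.Generator, p0: np.ndarray
) -> np.ndarray:
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    path = np.empty(n_frames, dtype=np.intp)
    s = int(rng.choice(n, p=p0))
    u = rng.random(n_frames)
    for t in range(n_frames):
        path[t] = s
        s = int(np.searchsorted(cum[s], u[t]))
    return path


def gen_hidden_markov_features(
    T_true: np.ndarray,
    state_means: np.ndarray,
    noise_sd: float,
    n_traj: int = 1,
    n_frames: int = 10_000,
    seed: int = 0,
) -> tuple[FeatureMatrix, list[np.ndarray], PlantedKinetics]:
    """Feature-level oracle: Gaussian emissions around hidden-state centroids.

    Hidden paths are simulated from ``T_true`` (started from its stationary
    distribution); each frame's features are the current state's centroid
    plus isotropic Gaussian noise.  Returns the feature matrix, per-trajectory
    hidden paths, and the exact kinetics.
    """
    T = _check_stochastic(T_true)
    if not np.allclose(T, np.eye(T.shape[0])):
        # the identity (fully absorbing) chain is allowed: the path simply
        # stays at its initial draw; any other reducible chain is rejected
        _check_irreducible(T)
    means = np.atleast_2d(np.asarray(state_means, dtype=float))
    if means.shape[0] != T.shape[0]:
        raise ValueError("one centroid row per hidden state required")
    if means.shape[0] > 1:
        d = np.linalg.norm(means[:, None] - means[None, :], axis=-1)
        if (d[~np.eye(len(means), dtype=bool)] == 0).any():
            raise ValueError("state centroids must be pairwise distinct")
    is_identity = np.allclose(T, np.eye(T.shape[0]))
    pi = np.full(T.shape[0], 1.0 / T.shape[0]) if is_identity else stationary_distribution(T)
    rng = np.random.default_rng(seed)
    blocks, paths = [], []
    for _ in range(n_traj):
        h = _simulate_chain(T, n_frames, rng, pi)
        x = means[h]
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=x.shape)
        blocks.append(x)
        paths.append(h)
    n_states = T.shape[0]
    mfpt = np.zeros((n_states, n_states))
    for i in range(n_states):
        for j in range(n_states):
            if i != j:
                mfpt[i, j] = np.inf if is_identity else true_mfpt(T, [i], [j])
    kin = PlantedKinetics(
        macrostates=[f"S{i}" for i in range(n_states)],
        T_true=T,
        pi_true=pi,
        mfpt_true=mfpt,
    )
    defs = [FeatureDefinition(1, j + 2) for j in range(means.shape[1])]
    fm = FeatureMatrix(np.concatenate(blocks), defs, [n_frames] * n_traj)
    return fm, paths, kin


# ---------------------------------------------------------------------------
# toy loop-bearing chain molecule

@dataclass(frozen=True)
class LoopBlock:
    """A contiguous mobile residue block with discrete conformations.

    ``first``/``last`` are 1-based inclusive residue bounds.  The block
    hops among ``n_conformations`` geometries under a symmetric chain that
    leaves the current conformation with probability ``switch_prob`` per
    frame (split equally among the alternatives).
    """

    first: int
    last: int
    switch_prob: float
    n_conformations: int = 2
    displacement: float = 6.0  # Å offset between successive conformations

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("first must be <= last")
        if not 0.0 <= self.switch_prob < 1.0:
            raise ValueError("switch_prob must be in [0, 1)")
        if self.n_conformations < 2:
            raise ValueError("need at least 2 conformations")

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(range(self.first, self.last + 1))

    def transition_matrix(self) -> np.ndarray:
        k, p = self.n_conformations, self.switch_prob
        T = np.full((k, k), p / (k - 1))
        np.fill_diagonal(T, 1.0 - p)
        return T


def _helix_backbone(n_residues: int) -> np.ndarray:
    """Bead positions along a helix with 3.8 Å spacing between neighbours."""
    radius, dtheta = 5.0, 0.6
    chord = 2.0 * radius * np.sin(dtheta / 2.0)
    rise = np.sqrt(3.8**2 - chord**2)
    k = np.arange(n_residues)
    theta = k * dtheta
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * k]
    )


def _conformation_offsets(
    base: np.ndarray, block: LoopBlock
) -> list[np.ndarray]:
    """Per-conformation coordinates of a block's residues.

    Conformation 0 sits on the backbone ("recessed"); conformation 1 is
    displaced radially outward ("extended"); any further conformation is
    displaced along the helix axis (a geometrically distinct bend).
    """
    rows = np.array([r - 1 for r in block.residues])
    coords = []
    for c in range(block.n_conformations):
        xyz = base[rows].copy()
        if c == 1:
            radial = xyz[:, :2]
            unit = radial / np.linalg.norm(radial, axis=1, keepdims=True)
            xyz[:, :2] += unit * block.displacement
        elif c >= 2:
            xyz[:, 2] += block.displacement * (c - 1)
            radial = xyz[:, :2]
            unit = radial / np.linalg.norm(radial, axis=1, keepdims=True)
            xyz[:, :2] += unit * block.displacement * 0.5
        coords.append(xyz)
    return coords


def gen_toy_loop_trajectory(
    n_residues: int = 40,
    loop_defs: Sequence[LoopBlock] | None = None,
    jitter_sd: float = 0.3,
    n_traj: int = 10,
    n_frames: int = 20_000,
    seed: int = 0,
    dt_ns: float = 1.0,
) -> SyntheticEnsemble:
    """Generate a bead-chain ensemble with two planted mobile loops.

    Defaults plant a fast block (residues 8–12, switch prob 0.01/frame) and
    a slow block (residues 28–33, switch prob 0.002/frame); their product
    chain has 4 macrostates with uniform stationary distribution.  Scaffold
    residues jitter isotropically (``jitter_sd``) about fixed helix
    positions; block residues jitter about their current conformation.
    """
    if loop_defs is None:
        loop_defs = (
            LoopBlock(8, 12, switch_prob=0.01),
            LoopBlock(28, 33, switch_prob=0.002),
        )
    if len(loop_defs) != 2:
        raise ValueError("exactly two loop blocks are required")
    b0, b1 = loop_defs
    if set(b0.residues) & set(b1.residues):
        raise ValueError("loop blocks must be disjoint")
    for b in (b0, b1):
        if b.first < 1 or b.last > n_residues:
            raise ValueError(f"block {b.first}-{b.last} outside chain 1..{n_residues}")

    base = _helix_backbone(n_residues)
    confs = [_conformation_offsets(base, b) for b in (b0, b1)]

    # separability: conformations of a block must differ by > 4*jitter_sd in
    # some distance to a scaffold residue
    scaffold = np.array(
        [r for r in range(n_residues) if (r + 1) not in b0.residues + b1.residues]
    )
    warning = False
    for bi, b in enumerate((b0, b1)):
        for a in range(b.n_conformations):
            for c in range(a + 1, b.n_conformations):
                da = np.linalg.norm(
                    confs[bi][a][:, None, :] - base[scaffold][None], axis=-1
                )
                dc = np.linalg.norm(
                    confs[bi][c][:, None, :] - base[scaffold][None], axis=-1
                )
                if np.abs(da - dc).max() <= 4.0 * jitter_sd:
                    warning = True

    T0, T1 = b0.transition_matrix(), b1.transition_matrix()
    k0, k1 = b0.n_conformations, b1.n_conformations
    T_prod = np.kron(T0, T1)  # product state = c0 * k1 + c1
    pi_prod = stationary_distribution(T_prod) if (b0.switch_prob > 0 and b1.switch_prob > 0) else np.kron(
        stationary_distribution(T0) if b0.switch_prob > 0 else np.full(k0, 1.0 / k0),
        stationary_distribution(T1) if b1.switch_prob > 0 else np.full(k1, 1.0 / k1),
    )
    n_states = k0 * k1
    mfpt = np.zeros((n_states, n_states))
    if b0.switch_prob > 0 and b1.switch_prob > 0:
        for i in range(n_states):
            for j in range(n_states):
                if i != j:
                    mfpt[i, j] = true_mfpt(T_prod, [i], [j])

    rng = np.random.default_rng(seed)
    rows0 = np.array([r - 1 for r in b0.residues])
    rows1 = np.array([r - 1 for r in b1.residues])
    trajs, hidden = [], []
    p0_0 = np.full(k0, 1.0 / k0)
    p0_1 = np.full(k1, 1.0 / k1)
    for _ in range(n_traj):
        h0 = _simulate_chain(T0, n_frames, rng, p0_0)
        h1 = _simulate_chain(T1, n_frames, rng, p0_1)
        xyz = np.broadcast_to(base, (n_frames, n_residues, 3)).copy()
        xyz[:, rows0, :] = np.stack(confs[0])[h0]
        xyz[:, rows1, :] = np.stack(confs[1])[h1]
        xyz += rng.normal(0.0, jitter_sd, size=xyz.shape)
        trajs.append(xyz)
        hidden.append(h0 * k1 + h1)

    topo = Topology(
        tuple((i + 1, "ALA", "A") for i in range(n_residues)), terminal_clip=0
    )
    slow, fast = (b0, b1) if b0.switch_prob <= b1.switch_prob else (b1, b0)
    labels = [f"B0c{i}|B1c{j}" for i in range(k0) for j in range(k1)]
    kin = PlantedKinetics(
        macrostates=labels,
        T_true=T_prod,
        pi_true=pi_prod,
        mfpt_true=mfpt,
        slow_loop_residues=slow.residues,
        fast_loop_residues=fast.residues,
    )
    ens = TrajectoryEnsemble(trajs, topo, dt_ns=dt_ns)
    return SyntheticEnsemble(ens, hidden, kin, seed, separability_warning=warning)


# ---------------------------------------------------------------------------
# relaxation forward generator

def gen_relaxation_data(truth: RelaxationTruth, seed: int = 0):
    """Forward-model an R1/R2/NOE table from known model-free parameters.

    Rates come from the Lipari–Szabo forward model at ``truth.field_MHz``
    plus Gaussian noise with the stated per-observable SD; the error
    columns are set to those SDs.  Returns a RelaxationDataset.
    """
    from .relaxation import RelaxationDataset, modelfree_forward

    n = len(truth.S2_true)
    rng = np.random.default_rng(seed)
    R1 = np.empty(n)
    R2 = np.empty(n)
    NOE = np.empty(n)
    for r in range(n):
        R1[r], R2[r], NOE[r] = modelfree_forward(
            S2=float(truth.S2_true[r]),
            tau_e_ps=float(truth.tau_e_true[r]),
            tau_m_ns=float(truth.tau_m_true),
            rex=float(truth.rex_true[r]),
            field_MHz=float(truth.field_MHz),
        )
    sd = truth.noise_sd
    if sd.get("R1", 0.0) > 0:
        R1 = R1 + rng.normal(0, sd["R1"], n)
    if sd.get("R2", 0.0) > 0:
        R2 = R2 + rng.normal(0, sd["R2"], n)
    if sd.get("NOE", 0.0) > 0:
        NOE = NOE + rng.normal(0, sd["NOE"], n)
    return RelaxationDataset(
        residue=np.arange(1, n + 1),
        R1=R1,
        R2=R2,
        NOE=NOE,
        R1_err=np.full(n, max(sd.get("R1", 0.0), 1e-6)),
        R2_err=np.full(n, max(sd.get("R2", 0.0), 1e-6)),
        NOE_err=np.full(n, max(sd.get("NOE", 0.0), 1e-6)),
        field_MHz=truth.field_MHz,
    )


# ---------------------------------------------------------------------------
# output writers

def write_ensemble(ens: SyntheticEnsemble, outdir: str | Path) -> dict:
    """Write PDB topology (+first frame), per-trajectory DCD, truth JSON."""
    import mdtraj as md

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topo = ens.ensemble.topology
    mtop = md.Topology()
    chain = mtop.add_chain()
    for idx, name, _ in topo.residues:
        res = mtop.add_residue(name, chain, resSeq=idx)
        mtop.add_atom("CA", md.element.carbon, res)
    paths = {"pdb": str(outdir / "topology.pdb"), "dcd": [], "truth": str(outdir / "truth.json")}
    first = md.Trajectory(ens.ensemble.trajectories[0][:1] / 10.0, mtop)
    first.save_pdb(paths["pdb"])
    for k, xyz in enumerate(ens.ensemble.trajectories):
        p = str(outdir / f"traj_{k:02d}.dcd")
        md.Trajectory(xyz / 10.0, mtop).save_dcd(p)
        paths["dcd"].append(p)
    ens.kinetics.to_json(paths["truth"])
    return paths
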