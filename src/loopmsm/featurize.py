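"""Cα pairwise-distance featurization of trajectory ensembles.

The analysis starts from an unbiased feature set: *every* Cα–Cα distance
between non-terminal residues.  Pairs that stay closer than ``d_min`` or
farther than ``d_max`` in every frame of every supplied system carry no
kinetic information and are pruned before any model fitting.  Per-residue
RMSF (after superposition onto the mean structure) summarises local
flexibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Topology",
    "TrajectoryEnsemble",
    "FeatureDefinition",
    "FeatureMatrix",
    "PruneReport",
    "load_topology",
    "load_trajectories",
    "enumerate_ca_pairs",
    "compute_features",
    "prune_features",
    "ca_rmsf",
]


@dataclass(frozen=True)
class Topology:
    """Residue-level topology: one entry per Cα.

    ``residues`` is an ordered list of ``(index, name, chain_id)`` with
    1-based, strictly increasing indices.  ``terminal_clip`` residues at
    each end are flagged as clipped and excluded from pair enumeration.
    """

    residues: tuple[tuple[int, str, str], ...]
    terminal_clip: int = 0

    def __post_init__(self) -> None:
        idx = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        if self.terminal_clip < 0:
            raise ValueError("terminal_clip must be >= 0")
        if 2 * self.terminal_clip >= len(self.residues):
            raise ValueError("terminal_clip removes all residues")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> np.ndarray:
        return np.array([r[0] for r in self.residues], dtype=int)

    def eligible_indices(self) -> np.ndarray:
        """Residue indices surviving the terminal clip."""
        c = self.terminal_clip
        return self.indices[c : self.n_residues - c if c else self.n_residues]

    def position_of(self, residue_index: int) -> int:
        """Array column of a 1-based residue index."""
        pos = int(np.searchsorted(self.indices, residue_index))
        if pos >= self.n_residues or self.indices[pos] != residue_index:
            raise KeyError(f"residue {residue_index} not in topology")
        return pos


@dataclass
class TrajectoryEnsemble:
    """One or more independent trajectories of Cα coordinates (Å).

    Each array has shape (frames, n_residues, 3); all trajectories share
    the topology.  ``dt_ns`` is the frame interval in nanoseconds.
    """

    trajectories: list[np.ndarray]
    topology: Topology
    dt_ns: float = 1.0

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("ensemble needs at least one trajectory")
        for i, xyz in enumerate(self.trajectories):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 3 or xyz.shape[2] != 3:
                raise ValueError(f"trajectory {i}: expected (frames, residues, 3)")
            if xyz.shape[1] != self.topology.n_residues:
                raise ValueError(
                    f"trajectory {i} has {xyz.shape[1]} residues, topology has "
                    f"{self.topology.n_residues}"
                )
            if xyz.shape[0] < 2:
                raise ValueError(f"trajectory {i} has fewer than 2 frames")
            if np.isnan(xyz).any():
                raise ValueError(f"trajectory {i} contains NaN coordinates")
            self.trajectories[i] = xyz

    @property
    def n_frames_total(self) -> int:
        return sum(t.shape[0] for t in self.trajectories)


@dataclass(frozen=True, order=True)
class FeatureDefinition:
    """An unordered residue pair (i < j, 1-based) labelled ``D_i_j``."""

    residue_i: int
    residue_j: int

    def __post_init__(self) -> None:
        if self.residue_i >= self.residue_j:
            raise ValueError("require residue_i < residue_j")

    @property
    def label(self) -> str:
        return f"D_{self.residue_i}_{self.residue_j}"

    @classmethod
    def from_label(cls, label: str) -> "FeatureDefinition":
        parts = label.split("_")
        if len(parts) != 3 or parts[0] != "D":
            raise ValueError(f"bad feature label {label!r}")
        return cls(int(parts[1]), int(parts[2]))


@dataclass
class FeatureMatrix:
    """Per-frame values of named distance features, segmented by trajectory."""

    values: np.ndarray  # (frames, features), Å
    definitions: list[FeatureDefinition]
    segment_lengths: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.definitions):
            raise ValueError("column count != number of definitions")
        if sum(self.segment_lengths) != self.values.shape[0]:
            raise ValueError("segment lengths must partition the rows")

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.definitions]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def segments(self) -> list[np.ndarray]:
        """Per-trajectory views of the value rows."""
        out, start = [], 0
        for n in self.segment_lengths:
            out.append(self.values[start : start + n])
            start += n
        return out

    def subset(self, labels: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given label order."""
        pos = {lab: k for k, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        cols = [pos[lab] for lab in labels]
        return FeatureMatrix(
            self.values[:, cols],
            [self.definitions[c] for c in cols],
            list(self.segment_lengths),
        )

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.to_csv(path, index=False, float_format="%.6f")
        if sidecar is not None:
            Path(sidecar).write_text(
                json.dumps({"segment_lengths": self.segment_lengths})
            )

    @classmethod
    def from_csv(
        cls, path: str | Path, sidecar: str | Path | None = None
    ) -> "FeatureMatrix":
        df = pd.read_csv(path)
        defs = [FeatureDefinition.from_label(c) for c in df.columns]
        if sidecar is not None:
            seg = json.loads(Path(sidecar).read_text())["segment_lengths"]
        else:
            seg = [len(df)]
        return cls(df.to_numpy(dtype=float), defs, seg)


@dataclass
class PruneReport:
    """Which features the distance-range rules removed and why."""

    removed_too_close: list[str] = field(default_factory=list)
    removed_too_far: list[str] = field(default_factory=list)
    d_min: float = 3.0
    d_max: float = 10.0

    @property
    def n_removed(self) -> int:
        return len(self.removed_too_close) + len(self.removed_too_far)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "d_min": self.d_min,
                    "d_max": self.d_max,
                    "removed_too_close": self.removed_too_close,
                    "removed_too_far": self.removed_too_far,
                },
                indent=1,
            )
        )


def load_topology(
    path: str | Path, chain: str | None = None, terminal_clip: int = 0
) -> Topology:
    """Read a PDB file and build a Cα topology.

    Parameters
    ----------
    path : PDB file with at least one chain containing Cα atoms.
    chain : chain id to select; required when the file has several chains.
    terminal_clip : residues at each end to flag as clipped.
    """
    import mdtraj as md

    top = md.load_topology(str(path))
    ca = top.select("name CA")
    if ca.size == 0:
        raise ValueError(f"{path}: no CA atoms found")
    atoms = [top.atom(int(a)) for a in ca]
    chains = sorted({a.residue.chain.chain_id or str(a.residue.chain.index) for a in atoms})
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"{path}: multiple chains {chains}; a chain selection is required"
            )
        chain = chains[0]
    atoms = [
        a
        for a in atoms
        if (a.residue.chain.chain_id or str(a.residue.chain.index)) == chain
    ]
    if not atoms:
        raise ValueError(f"{path}: chain {chain!r} has no CA atoms")
    residues = []
    seen: set[int] = set()
    for a in atoms:
        r = a.residue
        idx = r.resSeq
        if idx in seen:
            raise ValueError(f"{path}: duplicate residue index {idx} in chain {chain}")
        seen.add(idx)
        name = r.name + (r.insertion_code or "" if hasattr(r, "insertion_code") else "")
        residues.append((idx, name, chain))
    return Topology(tuple(residues), terminal_clip=terminal_clip)


def load_trajectories(
    paths: Sequence[str | Path],
    topology_pdb: str | Path,
    topology: Topology | None = None,
    stride: int = 1,
    dt_ns: float = 1.0,
) -> TrajectoryEnsemble:
    """Read DCD/XTC/PDB trajectories, extract Cα coordinates in Å.

    ``topology_pdb`` is the PDB the trajectories were written against;
    ``topology`` (optional) is a pre-built Cα topology to attach, otherwise
    one is derived from the PDB.  ``dt_ns`` is the frame interval before
    striding; it is scaled by ``stride``.
    """
    import mdtraj as md

    if not paths:
        raise ValueError("no trajectory paths given")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if topology is None:
        topology = load_topology(topology_pdb)
    ref = md.load_topology(str(topology_pdb))
    ca = ref.select("name CA")
    trajs = []
    for p in paths:
        t = md.load(str(p), top=str(topology_pdb), stride=stride)
        if t.n_atoms != ref.n_atoms:
            raise ValueError(
                f"{p}: atom count {t.n_atoms} does not match topology {ref.n_atoms}"
            )
        xyz = np.asarray(t.xyz[:, ca, :], dtype=float) * 10.0  # nm -> Å
        if xyz.shape[1] != topology.n_residues:
            raise ValueError(
                f"{p}: {xyz.shape[1]} CA atoms vs topology {topology.n_residues}"
            )
        trajs.append(xyz)
    return TrajectoryEnsemble(trajs, topology, dt_ns=dt_ns * stride)


def enumerate_ca_pairs(topology: Topology) -> list[FeatureDefinition]:
    """All unordered residue pairs over clip-surviving residues.

    Deterministic lexicographic order; with n eligible residues this yields
    n(n−1)/2 definitions (192 residues → 18 336).
    """
    eligible = topology.eligible_indices()
    if eligible.size < 2:
        raise ValueError("fewer than 2 eligible residues after terminal clip")
    return [
        FeatureDefinition(int(i), int(j))
        for a, i in enumerate(eligible)
        for j in eligible[a + 1 :]
    ]


def compute_features(
    ensemble: TrajectoryEnsemble, defs: Sequence[FeatureDefinition]
) -> FeatureMatrix:
    """Euclidean Cα–Cα distance (Å) per frame for every definition."""
    top = ensemble.topology
    try:
        cols_i = np.array([top.position_of(d.residue_i) for d in defs])
        cols_j = np.array([top.position_of(d.residue_j) for d in defs])
    except KeyError as e:
        raise ValueError(f"feature references residue outside topology: {e}") from e
    blocks, seg = [], []
    for xyz in ensemble.trajectories:
        diff = xyz[:, cols_i, :] - xyz[:, cols_j, :]
        blocks.append(np.sqrt(np.einsum("fkd,fkd->fk", diff, diff)))
        seg.append(xyz.shape[0])
    return FeatureMatrix(np.concatenate(blocks, axis=0), list(defs), seg)


def prune_features(
    fm: FeatureMatrix, d_min: float = 3.0, d_max: float = 10.0
) -> tuple[FeatureMatrix, PruneReport]:
    """Drop features that are consistently too close or too far.

    A feature is removed iff every frame is < ``d_min`` (too close) or every
    frame is > ``d_max`` (too far), evaluated over all rows passed in — when
    comparing two systems, concatenate their matrices first so both share
    one retained set.
    """
    if fm.n_frames == 0 or fm.n_features == 0:
        raise ValueError("empty feature matrix")
    col_max = fm.values.max(axis=0)
    col_min = fm.values.min(axis=0)
    too_close = col_max < d_min
    too_far = col_min > d_max
    keep = ~(too_close | too_far)
    report = PruneReport(
        removed_too_close=[fm.labels[k] for k in np.where(too_close)[0]],
        removed_too_far=[fm.labels[k] for k in np.where(too_far)[0]],
        d_min=d_min,
        d_max=d_max,
    )
    if not keep.any():
        raise ValueError(
            "all features pruned; review d_min/d_max thresholds for this system"
        )
    kept = FeatureMatrix(
        fm.values[:, keep],
        [d for d, k in zip(fm.definitions, keep) if k],
        list(fm.segment_lengths),
    )
    return kept, report


def _superpose(xyz: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rigid-body superposition of every frame onto ``ref`` (Kabsch)."""
    out = np.empty_like(xyz)
    ref_c = ref - ref.mean(axis=0)
    for f in range(xyz.shape[0]):
        x = xyz[f] - xyz[f].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, x)
        out[f] = rot.apply(x)
    return out


def ca_rmsf(ensemble: TrajectoryEnsemble, superpose: bool = True) -> np.ndarray:
    """Per-residue RMSF (Å) about the mean structure.

    Each trajectory is superposed onto its own mean structure (iterated
    once: mean → superpose → mean), then deviations are pooled across
    trajectories.
    """
    n_res = ensemble.topology.n_residues
    sq_sum = np.zeros(n_res)
    n_tot = 0
    for xyz in ensemble.trajectories:
        if xyz.shape[0] < 2:
            raise ValueError("RMSF needs at least 2 frames per trajectory")
        if superpose:
            # iterative mean-structure alignment, seeded from the first frame
            # so arbitrary per-frame rigid motion cannot corrupt the mean
            ref = xyz[0]
            aligned = xyz
            for _ in range(20):
                aligned = _superpose(xyz, ref)
                new_ref = aligned.mean(axis=0)
                if np.abs(new_ref - ref).max() < 1e-10:
                    ref = new_ref
                    break
                ref = new_ref
        else:
            aligned = xyz
        mean = aligned.mean(axis=0)
        sq_sum += ((aligned - mean) ** 2).sum(axis=(0, 2))
        n_tot += xyz.shape[0]
    return np.sqrt(sq_sum / n_tot)
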