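"""Two-system comparison in a shared kinetic coordinate space.

To compare, say, a wildtype-like and a mutant-like ensemble, both systems
must live in the same tICA space: covariances are accumulated over the
concatenated segment lists of both systems (never pairing frames across
systems), giving a single model that projects both.  Metastable states of
the two systems are then matched geometrically by their tIC centroids;
states without a counterpart within a distance threshold are declared
exclusive to their system.  Matched states yield population-shift and
MFPT-ratio tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurize import FeatureMatrix, TrajectoryEnsemble, compute_features
from .metastable import MetastableModel, macro_mfpt
from .tica import TICAModel, estimate_covariances, fit_tica_from_covariances, project_frame

__all__ = [
    "ComparisonReport",
    "joint_tica",
    "project_references",
    "match_macrostates",
    "compare_kinetics",
    "macrostate_centroids",
]


@dataclass
class MatchedPair:
    state_a: int
    state_b: int
    distance: float


@dataclass
class ComparisonReport:
    matched: list[MatchedPair]
    exclusive_a: list[int]
    exclusive_b: list[int]
    population_shift: list[dict] = field(default_factory=list)
    mfpt_ratio: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_states = [m.state_a for m in self.matched] + self.exclusive_a
        b_states = [m.state_b for m in self.matched] + self.exclusive_b
        if len(set(a_states)) != len(a_states) or len(set(b_states)) != len(b_states):
            raise ValueError("each macrostate must appear exactly once")


def joint_tica(
    fm_a: FeatureMatrix,
    fm_b: FeatureMatrix,
    lag: int,
    n_components: int | None = None,
    reg_epsilon: float = 1e-6,
) -> TICAModel:
    """One tICA model over both systems' segments (shared coordinate space).

    Requires identical feature label sets; covariance pairs never cross a
    segment boundary, hence never mix the systems' dynamics.
    """
    if set(fm_a.labels) != set(fm_b.labels):
        raise ValueError(
            "feature label mismatch between systems: "
            f"only_a={sorted(set(fm_a.labels) - set(fm_b.labels))} "
            f"only_b={sorted(set(fm_b.labels) - set(fm_a.labels))}"
        )
    if fm_b.labels != fm_a.labels:
        fm_b = fm_b.subset(fm_a.labels)
    combined = FeatureMatrix(
        np.concatenate([fm_a.values, fm_b.values]),
        list(fm_a.definitions),
        list(fm_a.segment_lengths) + list(fm_b.segment_lengths),
    )
    C0, Ct, mean = estimate_covariances(combined, lag)
    return fit_tica_from_covariances(
        C0, Ct, mean, lag, fm_a.labels, n_components, reg_epsilon
    )


def project_references(
    model: TICAModel,
    structures: list[TrajectoryEnsemble] | list[np.ndarray],
    defs,
    topology=None,
) -> list[np.ndarray | None]:
    """Project single reference conformations into the shared tIC space.

    Each structure is either a one-frame TrajectoryEnsemble or a raw
    (n_residues, 3) coordinate array (requires ``topology``).  A structure
    missing a required residue yields None for that entry; the others
    proceed.
    """
    out: list[np.ndarray | None] = []
    for s in structures:
        try:
            if isinstance(s, np.ndarray):
                if topology is None:
                    raise ValueError("topology required for raw coordinate arrays")
                ens = TrajectoryEnsemble(
                    [np.repeat(s[None], 2, axis=0)], topology
                )
            else:
                ens = s
            fm = compute_features(ens, defs)
            out.append(project_frame(model, fm.values[0], fm.labels))
        except (ValueError, KeyError):
            out.append(None)
    return out


def macrostate_centroids(
    model: MetastableModel, projected: np.ndarray, dtrajs: list[np.ndarray]
) -> np.ndarray:
    """Mean tIC coordinate of each macrostate (frame-weighted)."""
    labels = np.concatenate(model.assign(dtrajs))
    n = model.n_macrostates
    cent = np.zeros((n, projected.shape[1]))
    for m in range(n):
        sel = labels == m
        cent[m] = projected[sel].mean(axis=0) if sel.any() else np.nan
    return cent


def match_macrostates(
    centroids_a: np.ndarray,
    centroids_b: np.ndarray,
    populations_a: np.ndarray | None = None,
    populations_b: np.ndarray | None = None,
    threshold: float | None = None,
) -> ComparisonReport:
    """Greedy centroid matching of two systems' macrostates.

    Pairs are accepted closest-first; a pair farther apart than
    ``threshold`` (default: half the median inter-centroid distance over
    all cross pairs) leaves both states exclusive.  Ties are broken toward
    the higher-population state when populations are given.
    """
    na, nb = len(centroids_a), len(centroids_b)
    dist = np.linalg.norm(centroids_a[:, None] - centroids_b[None], axis=-1)
    if threshold is None:
        threshold = 0.5 * float(np.median(dist))
    pa = populations_a if populations_a is not None else np.zeros(na)
    pb = populations_b if populations_b is not None else np.zeros(nb)
    cand = sorted(
        ((dist[i, j], -(pa[i] + pb[j]), i, j) for i in range(na) for j in range(nb))
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for d, _, i, j in cand:
        if d > threshold:
            break
        if i in used_a or j in used_b:
            continue
        matched.append(MatchedPair(i, j, float(d)))
        used_a.add(i)
        used_b.add(j)
    return ComparisonReport(
        matched=matched,
        exclusive_a=sorted(set(range(na)) - used_a),
        exclusive_b=sorted(set(range(nb)) - used_b),
    )


def compare_kinetics(
    model_a: MetastableModel,
    model_b: MetastableModel,
    report: ComparisonReport,
    dt_ns: float = 1.0,
) -> ComparisonReport:
    """Fill population-shift and MFPT-ratio tables for matched states.

    ΔP = P_B − P_A per matched pair (with propagated bootstrap SDs when
    available); MFPT ratio = MFPT_A / MFPT_B for every ordered pair of
    matched states, omitted with a flag when either passage is undefined.
    """
    if not report.matched:
        raise ValueError("matching is empty")
    report.population_shift = []
    report.mfpt_ratio = []
    for m in report.matched:
        pa = float(model_a.populations[m.state_a])
        pb = float(model_b.populations[m.state_b])
        sa = model_a.population_sd[m.state_a] if model_a.population_sd is not None else np.nan
        sb = model_b.population_sd[m.state_b] if model_b.population_sd is not None else np.nan
        report.population_shift.append(
            {
                "state_a": m.state_a,
                "state_b": m.state_b,
                "P_a": pa,
                "P_b": pb,
                "delta": pb - pa,
                "delta_sd": float(np.sqrt(np.nan_to_num(sa) ** 2 + np.nan_to_num(sb) ** 2))
                if not (np.isnan(sa) and np.isnan(sb))
                else np.nan,
            }
        )
    for src in report.matched:
        for tgt in report.matched:
            if src is tgt:
                continue
            try:
                ma, _ = macro_mfpt(model_a, src.state_a, tgt.state_a, dt_ns)
                mb, _ = macro_mfpt(model_b, src.state_b, tgt.state_b, dt_ns)
            except ValueError:
                report.mfpt_ratio.append(
                    {"from_a": src.state_a, "to_a": tgt.state_a, "ratio": np.nan,
                     "flag": "unreachable"}
                )
                continue
            report.mfpt_ratio.append(
                {
                    "from_a": src.state_a,
                    "to_a": tgt.state_a,
                    "from_b": src.state_b,
                    "to_b": tgt.state_b,
                    "mfpt_a": ma,
                    "mfpt_b": mb,
                    "ratio": ma / mb,
                    "flag": "",
                }
            )
    return report
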