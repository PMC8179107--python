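"""Iterative kinetic feature selection.

Starting from an unbiased (all-pairs) distance feature set, the procedure
alternates two steps until a compact set remains:

1. fit tICA on the current features;
2. score each feature by its maximum absolute Pearson correlation with
   the first few tICs, and eliminate the low-scoring ones.

Because tICA is refit after every elimination, features that only echo
fast motions are progressively discarded while the combinations carrying
the slowest processes survive.  The residues that recur among the
surviving pairs are reported as "anchor" residues — the positions whose
geometry encodes the slow conformational exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurize import FeatureDefinition, FeatureMatrix
from .tica import feature_tic_correlation, fit_tica

__all__ = ["SelectionConfig", "SelectionResult", "iterative_tica_selection",
           "anchor_report"]


@dataclass
class SelectionConfig:
    """Parameters of the iterative selection loop.

    Elimination: drop the lowest-scoring fraction (1 − keep_fraction) each
    iteration while more than 2·target_n_features remain, then drop one
    feature at a time; alternatively drop all features whose score falls
    below ``min_correlation``.  Stops at ``target_n_features`` or when
    ``max_iterations`` is reached.
    """

    lag: int = 50
    n_tics_considered: int = 2
    keep_fraction: float = 0.5
    min_correlation: float | None = None
    target_n_features: int = 24
    max_iterations: int = 100
    reg_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_fraction < 1.0:
            raise ValueError("keep_fraction must be in (0, 1)")
        if self.min_correlation is not None and not 0.0 <= self.min_correlation < 1.0:
            raise ValueError("min_correlation must be in [0, 1)")
        if self.target_n_features < 2:
            raise ValueError("target_n_features must be >= 2")


@dataclass
class IterationRecord:
    n_features: int
    min_score: float
    max_score: float
    slowest_timescale: float


@dataclass
class SelectionResult:
    selected: list[FeatureDefinition]
    log: list[IterationRecord] = field(default_factory=list)
    status: str = "converged"

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.selected]

    @property
    def anchor_table(self) -> dict[int, int]:
        """Residue → number of selected pairs containing it, sorted by count."""
        counts: dict[int, int] = {}
        for d in self.selected:
            counts[d.residue_i] = counts.get(d.residue_i, 0) + 1
            counts[d.residue_j] = counts.get(d.residue_j, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def _scores(fm: FeatureMatrix, cfg: SelectionConfig):
    model = fit_tica(fm, lag=cfg.lag, reg_epsilon=cfg.reg_epsilon)
    n_tics = min(cfg.n_tics_considered, model.n_components)
    corr = feature_tic_correlation(model, fm, n_tics=n_tics)
    return np.abs(corr).max(axis=1), model


def iterative_tica_selection(
    fm: FeatureMatrix, cfg: SelectionConfig | None = None
) -> SelectionResult:
    """Run the alternating tICA-fit / low-correlation-elimination loop.

    Deterministic: score ties are broken by lexicographic feature label
    (later labels dropped first).  If an elimination step would overshoot
    below the target count it is clamped to exactly the target.
    """
    cfg = cfg or SelectionConfig()
    current = fm
    log: list[IterationRecord] = []
    status = "converged"
    K = cfg.target_n_features
    for _ in range(cfg.max_iterations):
        if current.n_features <= K:
            break
        scores, model = _scores(current, cfg)
        log.append(
            IterationRecord(
                n_features=current.n_features,
                min_score=float(scores.min()),
                max_score=float(scores.max()),
                slowest_timescale=float(model.timescales[0]),
            )
        )
        if np.allclose(scores, scores[0]):
            status = "stalled"
            break
        # stable order: score ascending, label descending among ties, so the
        # lexicographically later feature is dropped first
        labels = current.labels
        order = sorted(range(len(scores)), key=lambda k: (scores[k], tuple(-ord(c) for c in labels[k])))
        if cfg.min_correlation is not None:
            n_drop = int(np.sum(scores < cfg.min_correlation))
            if n_drop == 0:
                status = "threshold_reached"
                break
        else:
            if current.n_features > 2 * K:
                n_drop = int(np.floor(current.n_features * (1.0 - cfg.keep_fraction)))
                n_drop = max(n_drop, 1)
            else:
                n_drop = 1
        n_drop = min(n_drop, current.n_features - K)  # clamp at target
        drop = set(order[:n_drop])
        keep_labels = [lab for k, lab in enumerate(labels) if k not in drop]
        current = current.subset(keep_labels)
    else:
        status = "max_iterations"
    return SelectionResult(selected=list(current.definitions), log=log, status=status)


def anchor_report(
    selected: list[FeatureDefinition], threshold: int = 2
) -> list[tuple[int, int]]:
    """Residues occurring in >= threshold selected pairs.

    Returns (residue, count) sorted by count descending, then index.
    """
    if not selected:
        raise ValueError("empty selection")
    table = SelectionResult(selected=selected).anchor_table
    return [(r, c) for r, c in table.items() if c >= threshold]
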