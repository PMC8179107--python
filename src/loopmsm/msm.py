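"""Microstate Markov state models.

Frames projected onto the leading tICs are discretized by k-means;
transition counts at a lag time feed a reversible maximum-likelihood
transition matrix, whose eigenvalues give the relaxation (implied)
timescales t_k = −τ/ln λ_k.  Validation is by lag-dependence of the
timescales and the Chapman–Kolmogorov test.  The same projected
coordinates yield free-energy surfaces F = −kT ln p̂ on a 2-D grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

__all__ = [
    "DiscreteTrajectories",
    "MarkovStateModel",
    "FreeEnergySurface",
    "cluster_microstates",
    "count_matrix",
    "largest_connected_set",
    "estimate_reversible_msm",
    "implied_timescales",
    "ck_test",
    "free_energy_surface",
]


@dataclass
class DiscreteTrajectories:
    dtrajs: list[np.ndarray]
    centers: np.ndarray          # (n_states, n_dims) in tIC coordinates
    seed: int = 0

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]

    def __post_init__(self) -> None:
        for d in self.dtrajs:
            if d.min() < 0 or d.max() >= self.n_states:
                raise ValueError("labels outside [0, n_states)")


@dataclass
class MarkovStateModel:
    lag: int
    active_set: np.ndarray       # microstate indices retained
    counts: np.ndarray           # on active set
    T: np.ndarray                # reversible row-stochastic
    pi: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("T rows must sum to 1")
        db = self.pi[:, None] * self.T - (self.pi[:, None] * self.T).T
        if np.abs(db).max() > 1e-8:
            raise ValueError("detailed balance violated beyond tolerance")

    @property
    def eigenvalues(self) -> np.ndarray:
        # reversible T is self-adjoint in the pi-weighted inner product
        s = np.sqrt(self.pi)
        sym = (s[:, None] * self.T) / s[None, :]
        lam = np.linalg.eigvalsh(0.5 * (sym + sym.T))
        return lam[::-1]

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales (frames) of the non-stationary eigenvalues."""
        lam = self.eigenvalues[1:]
        if n is not None:
            lam = lam[:n]
        out = np.zeros(len(lam))
        ok = (lam > 0) & (lam < 1)
        out[ok] = -self.lag / np.log(lam[ok])
        out[lam >= 1] = np.inf
        return out


@dataclass
class FreeEnergySurface:
    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray                # kT units, min 0, NaN on empty bins
    mask: np.ndarray             # True where empty

    @property
    def minimum(self) -> float:
        return float(np.nanmin(self.F))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.F).to_csv(path, index=False, header=False)


def cluster_microstates(
    projected: np.ndarray | list[np.ndarray], k: int, seed: int = 0
) -> DiscreteTrajectories:
    """k-means discretization of projected coordinates (k-means++ init)."""
    if isinstance(projected, np.ndarray):
        projected = [projected]
    lengths = [p.shape[0] for p in projected]
    X = np.concatenate([np.atleast_2d(p.T).T for p in projected])
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds total frames {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=3, random_state=seed)
    labels = km.fit_predict(X)
    dtrajs, start = [], 0
    for n in lengths:
        dtrajs.append(labels[start : start + n].astype(np.intp))
        start += n
    return DiscreteTrajectories(dtrajs, km.cluster_centers_, seed=seed)


def count_matrix(
    dtrajs: list[np.ndarray] | DiscreteTrajectories,
    lag: int,
    n_states: int | None = None,
) -> np.ndarray:
    """Sliding-window transition counts C_ij at the given lag.

    Pairs never cross trajectory boundaries; counts from separate
    trajectories add.
    """
    if isinstance(dtrajs, DiscreteTrajectories):
        n_states = dtrajs.n_states
        dtrajs = dtrajs.dtrajs
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if min(len(d) for d in dtrajs) <= lag:
        raise ValueError("lag must be shorter than every trajectory")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states))
    for d in dtrajs:
        np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    return C


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """Strongly connected component with the greatest total counts."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    n_comp, labels = connected_components(
        counts > 0, directed=True, connection="strong"
    )
    totals = [counts[np.ix_(labels == c, labels == c)].sum() for c in range(n_comp)]
    best = int(np.argmax(totals))
    return np.where(labels == best)[0]


def estimate_reversible_msm(
    counts: np.ndarray,
    lag: int,
    active_set: np.ndarray | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 1_000_000,
) -> MarkovStateModel:
    """Maximum-likelihood reversible transition matrix from counts.

    Self-consistent fixed-point iteration on the unnormalized flux
    x_ij = π_i T_ij:  x_ij ∝ (C_ij + C_ji) / (c_i/x_i + c_j/x_j), iterated
    until the max relative change of x drops below ``tol``; π is recovered
    from the row sums of x.
    """
    counts = np.asarray(counts, dtype=float)
    if active_set is None:
        active_set = largest_connected_set(counts)
    C = counts[np.ix_(active_set, active_set)]
    n_comp, _ = connected_components(C > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("count matrix not irreducible on the active set")
    c_row = C.sum(axis=1)
    Csym = C + C.T
    x = Csym / Csym.sum()
    for sweep in range(max_sweeps):
        xi = x.sum(axis=1)
        q = c_row / xi
        denom = q[:, None] + q[None, :]
        x_new = np.where(Csym > 0, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        delta = np.abs(x_new - x).max() / max(x.max(), 1e-300)
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_sweeps} sweeps "
            f"(residual {delta:.2e})"
        )
    pi = x.sum(axis=1)
    T = x / pi[:, None]
    T = T / T.sum(axis=1, keepdims=True)
    pi = pi / pi.sum()
    return MarkovStateModel(lag=lag, active_set=np.asarray(active_set),
                            counts=C, T=T, pi=pi)


def implied_timescales(
    dtrajs: list[np.ndarray] | DiscreteTrajectories,
    lags: list[int],
    n_its: int = 5,
    dt_ns: float = 1.0,
) -> pd.DataFrame:
    """Implied-timescale table: one row per lag, columns t1..t_n (× dt units).

    Per-lag estimation failures are recorded as NaN rows, not raised.
    """
    rows = []
    for lag in lags:
        try:
            C = count_matrix(dtrajs, lag)
            model = estimate_reversible_msm(C, lag)
            ts = model.timescales(n_its) * dt_ns
            ts = np.pad(ts.astype(float), (0, max(0, n_its - len(ts))),
                        constant_values=np.nan)
        except (ValueError, RuntimeError):
            ts = np.full(n_its, np.nan)
        rows.append([lag] + list(ts[:n_its]))
    return pd.DataFrame(rows, columns=["lag"] + [f"t{k+1}" for k in range(n_its)])


def ck_test(
    msm: MarkovStateModel,
    dtrajs: list[np.ndarray] | DiscreteTrajectories,
    macro_sets: list[list[int]],
    factors: list[int],
) -> pd.DataFrame:
    """Chapman–Kolmogorov test on groups of microstates.

    Compares set-occupation probabilities predicted by T(τ)^f against an
    MSM re-estimated at lag f·τ.  Returns per (set, factor) the predicted
    and estimated probabilities and their absolute deviation.
    """
    rows = []
    pos = {int(s): k for k, s in enumerate(msm.active_set)}
    for f in factors:
        Tf = np.linalg.matrix_power(msm.T, f)
        est = estimate_reversible_msm(count_matrix(dtrajs, msm.lag * f), msm.lag * f)
        est_pos = {int(s): k for k, s in enumerate(est.active_set)}
        for si, states in enumerate(macro_sets):
            a = [pos[s] for s in states if s in pos]
            w = msm.pi[a] / msm.pi[a].sum()
            pred = float(np.sum(w[:, None] * Tf[np.ix_(a, a)]))
            b = [est_pos[s] for s in states if s in est_pos]
            w2 = est.pi[b] / est.pi[b].sum()
            meas = float(np.sum(w2[:, None] * est.T[np.ix_(b, b)]))
            rows.append((si, f, pred, meas, abs(pred - meas)))
    return pd.DataFrame(
        rows, columns=["set", "factor", "predicted", "estimated", "deviation"]
    )


def free_energy_surface(
    projected: np.ndarray,
    bins: int = 50,
    kT: float = 1.0,
    weights: np.ndarray | None = None,
) -> FreeEnergySurface:
    """F = −kT ln p̂ on a 2-D histogram of (tIC1, tIC2), min shifted to 0."""
    projected = np.asarray(projected)
    if projected.ndim != 2 or projected.shape[1] < 2:
        raise ValueError("need at least 2 projected components")
    if bins < 10:
        raise ValueError("use at least 10 bins per axis")
    H, xe, ye = np.histogram2d(
        projected[:, 0], projected[:, 1], bins=bins, weights=weights
    )
    if (H > 0).sum() <= 1:
        raise ValueError("all frames fall in one bin; review binning")
    p = H / H.sum()
    mask = p == 0
    with np.errstate(divide="ignore"):
        F = -kT * np.log(np.where(mask, np.nan, p))
    F -= np.nanmin(F)
    return FreeEnergySurface(xe, ye, F, mask)
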