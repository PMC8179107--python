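"""Metastable-state coarse-graining of microstate models.

The microstate transition matrix is coarse-grained into a handful of
metastable macrostates: PCCA+ (spectral clustering of the dominant
eigenvectors of the reversible transition matrix into fuzzy memberships)
supplies the initial hidden-state structure, and a discrete-output hidden
Markov model refined by Baum–Welch yields the final hidden transition
matrix, output probabilities and equilibrium populations.  Uncertainties
come from a bootstrap over whole trajectories; macrostate mean first
passage times are computed on the hidden transition matrix by a linear
solve.

The number of macrostates is chosen from the implied-timescale spectrum:
a large gap between t_k and t_{k+1} indicates k slow processes, hence
k + 1 metastable states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .msm import (
    DiscreteTrajectories,
    MarkovStateModel,
    count_matrix,
    estimate_reversible_msm,
)
from .synthetic import stationary_distribution, true_mfpt

__all__ = [
    "MetastableModel",
    "select_macrostate_count",
    "pcca_memberships",
    "coarse_grain_hmm",
    "population_uncertainty",
    "macro_mfpt",
]


@dataclass
class MetastableModel:
    n_macrostates: int
    lag: int
    memberships: np.ndarray          # (micro, macro), rows sum to 1
    T_coarse: np.ndarray             # hidden transition matrix at lag
    populations: np.ndarray
    population_sd: np.ndarray | None
    emission: np.ndarray             # (macro, micro) observation probs
    micro_states: np.ndarray         # active microstate indices
    mfpt_frames: np.ndarray          # (macro, macro), frames
    dt_ns: float = 1.0
    bootstrap_T: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.memberships.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("membership rows must sum to 1")
        if not np.allclose(self.populations.sum(), 1.0, atol=1e-8):
            raise ValueError("populations must sum to 1")
        if not np.allclose(np.diag(self.mfpt_frames), 0.0):
            raise ValueError("MFPT diagonal must be 0")

    @property
    def slowest_timescale_frames(self) -> float:
        lam = np.sort(np.abs(np.linalg.eigvals(self.T_coarse)))[::-1]
        if len(lam) < 2 or not (0 < lam[1] < 1):
            return np.inf
        return float(-self.lag / np.log(lam[1]))

    def slowest_timescale_sd_frames(self) -> float:
        """SD of the slowest timescale over the bootstrap replicas."""
        if not self.bootstrap_T:
            raise ValueError("no bootstrap replicas attached")
        vals = []
        for T in self.bootstrap_T:
            lam = np.sort(np.abs(np.linalg.eigvals(T)))[::-1]
            if len(lam) > 1 and 0 < lam[1] < 1:
                vals.append(-self.lag / np.log(lam[1]))
        return float(np.std(vals)) if vals else np.nan

    def assign(self, dtrajs: list[np.ndarray]) -> list[np.ndarray]:
        """Per-frame macrostate labels by argmax membership of the microstate."""
        lut = np.full(int(self.micro_states.max()) + 1, -1, dtype=np.intp)
        lut[self.micro_states] = np.argmax(self.memberships, axis=1)
        fallback = int(np.argmax(self.memberships.sum(axis=0)))
        out = []
        for d in dtrajs:
            lab = np.where(d < len(lut), lut[np.minimum(d, len(lut) - 1)], -1)
            lab = np.where(lab < 0, fallback, lab)
            out.append(lab.astype(np.intp))
        return out


def select_macrostate_count(
    its_table, n_override: int | None = None, min_ratio: float = 1.5
) -> int:
    """Pick the macrostate count from a timescale spectrum via the gap rule.

    ``its_table`` is either a 1-D array of timescales (slowest first) or the
    DataFrame from :func:`loopmsm.msm.implied_timescales`, in which case the
    last (largest-lag) row is used.  Returns 1 + argmax of the ratio
    t_k/t_{k+1}; an explicit ``n_override`` always wins.
    """
    if n_override is not None:
        return int(n_override)
    ts = np.asarray(its_table, dtype=float) if not hasattr(its_table, "columns") else (
        its_table.iloc[-1, 1:].to_numpy(dtype=float)
    )
    ts = ts[np.isfinite(ts) & (ts > 0)]
    if len(ts) < 2:
        raise ValueError("need at least 2 finite timescales")
    ratios = ts[:-1] / ts[1:]
    if (ratios < min_ratio).all():
        raise ValueError(
            "no clear timescale gap (all ratios < "
            f"{min_ratio}); pass an explicit macrostate count"
        )
    return int(np.argmax(ratios)) + 2


def pcca_memberships(msm: MarkovStateModel, n_macro: int) -> np.ndarray:
    """PCCA+ fuzzy memberships from the dominant eigenvectors.

    The top ``n_macro`` right eigenvectors of the reversible transition
    matrix span a simplex whose vertices correspond to the metastable
    states; memberships are the barycentric coordinates of each microstate
    in that simplex (inner-simplex vertex search, negative coordinates
    clipped and rows renormalized).
    """
    if n_macro < 2:
        raise ValueError("n_macro must be >= 2")
    if n_macro > msm.T.shape[0]:
        raise ValueError("more macrostates than microstates")
    s = np.sqrt(msm.pi)
    sym = 0.5 * ((s[:, None] * msm.T) / s[None, :] + ((s[:, None] * msm.T) / s[None, :]).T)
    lam, v = np.linalg.eigh(sym)
    order = np.argsort(lam)[::-1][:n_macro]
    X = v[:, order] / s[:, None]
    X /= X[:, 0:1]  # first column exactly 1
    # inner-simplex vertex search
    verts = [int(np.argmax(np.linalg.norm(X, axis=1)))]
    Y = X - X[verts[0]]
    for _ in range(1, n_macro):
        norms = np.linalg.norm(Y, axis=1)
        nxt = int(np.argmax(norms))
        verts.append(nxt)
        w = Y[nxt] / norms[nxt]
        Y = Y - np.outer(Y @ w, w)
    A = np.linalg.inv(X[verts])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return chi


def _coarse_grain_T(msm: MarkovStateModel, chi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Membership-projected coarse transition matrix and emission probs."""
    D = msm.pi[:, None] * chi                  # (micro, macro) joint weights
    pi_macro = D.sum(axis=0)
    W = (chi.T * msm.pi) @ chi                 # macro-space mass matrix
    Tc = np.linalg.solve(W, (chi.T * msm.pi) @ msm.T @ chi)
    Tc = np.clip(Tc, 0.0, None)
    Tc /= Tc.sum(axis=1, keepdims=True)
    B = (D / pi_macro[None, :]).T              # (macro, micro)
    B = np.clip(B, 1e-12, None)
    B /= B.sum(axis=1, keepdims=True)
    return Tc, B


def _strided_observations(
    dtrajs: list[np.ndarray], lut: np.ndarray, lag: int
) -> list[np.ndarray]:
    obs = []
    for d in dtrajs:
        o = lut[d[::lag]]
        if len(o) >= 2:
            obs.append(o)
    if not obs:
        raise ValueError("no observation sequence longer than the lag")
    return obs


def coarse_grain_hmm(
    dtrajs: list[np.ndarray] | DiscreteTrajectories,
    n_macrostates: int,
    lag: int,
    seed: int = 0,
    n_boot: int = 0,
    dt_ns: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MetastableModel:
    """PCCA+-initialized hidden Markov coarse-graining at the given lag.

    A reversible microstate MSM is estimated, PCCA+ gives initial fuzzy
    memberships, and Baum–Welch (discrete output distributions, observed
    at stride = lag) refines the hidden transition and emission matrices
    until the log-likelihood gain is below ``tol``.  Populations are the
    stationary distribution of the hidden transition matrix.  With
    ``n_boot`` > 0, a trajectory bootstrap supplies population SDs.
    """
    if isinstance(dtrajs, DiscreteTrajectories):
        dtrajs = dtrajs.dtrajs
    if n_macrostates < 2:
        raise ValueError("n_macrostates must be >= 2")
    model = _fit_hmm_once(dtrajs, n_macrostates, lag, seed, tol, max_iter, dt_ns)
    if n_boot > 0:
        sd, reps = population_uncertainty(
            dtrajs, n_macrostates, lag, n_boot=n_boot, seed=seed,
            reference=model, tol=tol, max_iter=max_iter,
        )
        model.population_sd = sd
        model.bootstrap_T = reps
    return model


def _fit_hmm_once(
    dtrajs: list[np.ndarray],
    n_macro: int,
    lag: int,
    seed: int,
    tol: float,
    max_iter: int,
    dt_ns: float,
    crisp_init: bool = False,
) -> MetastableModel:
    from hmmlearn.hmm import CategoricalHMM

    C = count_matrix(dtrajs, lag)
    msm = estimate_reversible_msm(C, lag)
    chi = pcca_memberships(msm, n_macro)
    if crisp_init:
        hard = np.argmax(chi, axis=1)
        chi = np.eye(n_macro)[hard]
        chi = 0.999 * chi + 0.001 / n_macro
        chi /= chi.sum(axis=1, keepdims=True)
    Tc, B = _coarse_grain_T(msm, chi)

    n_active = len(msm.active_set)
    lut = np.full(int(max(d.max() for d in dtrajs)) + 1, -1, dtype=np.intp)
    lut[msm.active_set] = np.arange(n_active)
    most_pop = int(np.argmax(msm.pi))
    lut[lut < 0] = most_pop  # rare off-active frames mapped to densest state
    obs = _strided_observations(dtrajs, lut, lag)
    X = np.concatenate(obs)[:, None]
    lengths = [len(o) for o in obs]

    hmm = CategoricalHMM(
        n_components=n_macro, n_features=n_active,
        init_params="", params="ste", tol=tol, n_iter=max_iter,
        random_state=seed,
    )
    hmm.startprob_ = stationary_distribution(Tc)
    hmm.transmat_ = Tc
    hmm.emissionprob_ = B
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm.fit(X, lengths)
    Th = np.asarray(hmm.transmat_)
    ok = np.all(np.isfinite(Th)) and np.allclose(Th.sum(axis=1), 1.0, atol=1e-6)
    pi_h = stationary_distribution(Th / Th.sum(axis=1, keepdims=True)) if ok else None
    if not ok or pi_h.min() < 1e-8:
        if not crisp_init:
            return _fit_hmm_once(dtrajs, n_macro, lag, seed, tol, max_iter,
                                 dt_ns, crisp_init=True)
        raise RuntimeError("Baum–Welch produced an empty or invalid macrostate")
    Th = Th / Th.sum(axis=1, keepdims=True)
    Bh = np.asarray(hmm.emissionprob_)
    # posterior memberships of each microstate given the hidden stationary law
    joint = pi_h[:, None] * Bh                       # (macro, micro)
    memb = (joint / np.clip(joint.sum(axis=0, keepdims=True), 1e-300, None)).T
    mfpt = np.zeros((n_macro, n_macro))
    for i in range(n_macro):
        for j in range(n_macro):
            if i != j:
                mfpt[i, j] = true_mfpt(Th, [i], [j]) * lag
    return MetastableModel(
        n_macrostates=n_macro,
        lag=lag,
        memberships=memb,
        T_coarse=Th,
        populations=pi_h,
        population_sd=None,
        emission=Bh,
        micro_states=msm.active_set,
        mfpt_frames=mfpt,
        dt_ns=dt_ns,
    )


def _match_macrostates(ref: MetastableModel, other: MetastableModel) -> np.ndarray:
    """Permutation aligning ``other``'s macrostates to ``ref`` by membership overlap."""
    common = np.intersect1d(ref.micro_states, other.micro_states)
    ri = np.searchsorted(ref.micro_states, common)
    oi = np.searchsorted(other.micro_states, common)
    overlap = ref.memberships[ri].T @ other.memberships[oi]
    _, cols = linear_sum_assignment(-overlap)
    return cols


def population_uncertainty(
    dtrajs: list[np.ndarray] | DiscreteTrajectories,
    n_macrostates: int,
    lag: int,
    n_boot: int = 100,
    seed: int = 0,
    reference: MetastableModel | None = None,
    estimator: str = "hmm",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Bootstrap SD of macrostate populations.

    Resamples whole trajectories with replacement (single trajectory:
    contiguous-block bootstrap with a warning), refits the coarse model,
    matches macrostates to the reference by maximal membership overlap,
    and returns (per-macrostate SD, list of matched replica hidden T).
    """
    if isinstance(dtrajs, DiscreteTrajectories):
        dtrajs = dtrajs.dtrajs
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    units = list(dtrajs)
    if len(units) == 1:
        warnings.warn(
            "single trajectory: falling back to contiguous-block bootstrap",
            stacklevel=2,
        )
        d = units[0]
        n_blocks = 10
        edges = np.linspace(0, len(d), n_blocks + 1, dtype=int)
        units = [d[a:b] for a, b in zip(edges[:-1], edges[1:]) if b - a > lag]
    if reference is None:
        reference = _fit_hmm_once(dtrajs, n_macrostates, lag, seed, tol,
                                  max_iter, 1.0)
    rng = np.random.default_rng(seed)
    pops, reps = [], []
    attempts = 0
    while len(pops) < n_boot and attempts < 3 * n_boot:
        attempts += 1
        pick = rng.integers(0, len(units), size=len(units))
        sample = [units[k] for k in pick]
        try:
            if estimator == "hmm":
                m = _fit_hmm_once(sample, n_macrostates, lag,
                                  seed + attempts, tol, max_iter, 1.0)
            else:  # "pcca": membership-weighted stationary populations
                msm = estimate_reversible_msm(count_matrix(sample, lag), lag)
                chi = pcca_memberships(msm, n_macrostates)
                Tc, B = _coarse_grain_T(msm, chi)
                m = MetastableModel(
                    n_macrostates, lag, chi, Tc,
                    (msm.pi[:, None] * chi).sum(axis=0), None, B,
                    msm.active_set,
                    np.zeros((n_macrostates, n_macrostates)),
                )
        except (ValueError, RuntimeError):
            continue
        perm = _match_macrostates(reference, m)
        pops.append(m.populations[perm])
        reps.append(m.T_coarse[np.ix_(perm, perm)])
    if len(pops) < max(2, n_boot // 2):
        raise RuntimeError("too many bootstrap replicas failed to fit")
    return np.std(np.asarray(pops), axis=0, ddof=1), reps


def macro_mfpt(
    model: MetastableModel,
    source: int | list[int],
    target: int | list[int],
    dt_ns: float | None = None,
) -> tuple[float, float]:
    """Macrostate MFPT in physical time, with bootstrap SD when available.

    Computed by the linear first-passage solve on the hidden transition
    matrix, scaled by lag × dt.  Returns (mfpt, sd); sd is NaN without
    bootstrap replicas.
    """
    dt = model.dt_ns if dt_ns is None else dt_ns
    src = [source] if np.isscalar(source) else list(source)
    tgt = [target] if np.isscalar(target) else list(target)
    val = true_mfpt(model.T_coarse, src, tgt) * model.lag * dt
    if model.bootstrap_T:
        vals = []
        for T in model.bootstrap_T:
            try:
                vals.append(true_mfpt(T, src, tgt) * model.lag * dt)
            except ValueError:
                continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
    else:
        sd = np.nan
    return float(val), sd
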