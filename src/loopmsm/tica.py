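"""Time-lagged independent component analysis (tICA).

tICA finds the linear combinations of input features with the slowest
autocorrelation: it solves the generalized eigenproblem
C(τ) v = λ C(0) v, where C(0) is the instantaneous and C(τ) the
time-lagged covariance of the mean-free features.  Eigenvalues (sorted
descending) give implied timescales t_k = −τ / ln λ_k; eigenvectors are
the feature loadings of the components (tICs), tIC1 being the slowest.

The lagged covariance is symmetrized, which enforces reversibility —
appropriate for equilibrium trajectory data feeding a Markov state model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .featurize import FeatureMatrix

__all__ = ["TICAModel", "estimate_covariances", "fit_tica", "project",
           "feature_tic_correlation"]


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray                 # feature means
    eigenvalues: np.ndarray          # descending
    eigenvectors: np.ndarray         # (features, components), C0-orthonormal
    labels: list[str]
    rank_deficient: bool = False

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def timescales(self) -> np.ndarray:
        """Implied timescales t_k = −τ/ln λ_k (frames); ∞ if λ≥1, 0 if λ≤0."""
        lam = self.eigenvalues
        out = np.zeros_like(lam)
        with np.errstate(divide="ignore"):
            ok = (lam > 0) & (lam < 1)
            out[ok] = -self.lag / np.log(lam[ok])
        out[lam >= 1] = np.inf
        return out


def estimate_covariances(
    fm: FeatureMatrix, lag: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-free instantaneous and symmetrized lagged covariances.

    Time pairs (t, t+lag) never cross trajectory segment boundaries.
    Returns (C0, Ctau, mean).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    short = [k for k, n in enumerate(fm.segment_lengths) if n <= lag]
    if short:
        raise ValueError(f"segments {short} are not longer than lag {lag}")
    segs = fm.segments()
    # symmetric estimator: means over both ends of the lagged pairs
    n_pairs = sum(s.shape[0] - lag for s in segs)
    mean = np.zeros(fm.n_features)
    for s in segs:
        mean += s[:-lag].sum(axis=0) + s[lag:].sum(axis=0)
    mean /= 2.0 * n_pairs
    C0 = np.zeros((fm.n_features, fm.n_features))
    Ct = np.zeros_like(C0)
    for s in segs:
        a = s[:-lag] - mean
        b = s[lag:] - mean
        C0 += a.T @ a + b.T @ b
        Ct += a.T @ b
    C0 /= 2.0 * n_pairs
    Ct /= n_pairs
    Ct = 0.5 * (Ct + Ct.T)
    return C0, Ct, mean


def fit_tica(
    fm: FeatureMatrix,
    lag: int,
    n_components: int | None = None,
    reg_epsilon: float = 1e-6,
) -> TICAModel:
    """Fit a tICA model on a feature matrix at the given lag (frames).

    ``reg_epsilon`` scales a ridge term reg_epsilon·(tr C0 / d) added to
    C0's diagonal before the generalized eigensolve; required when the
    feature set is rank-deficient (e.g. an all-pairs first pass).
    """
    C0, Ct, mean = estimate_covariances(fm, lag)
    model = _solve_tica(C0, Ct, mean, lag, fm.labels, n_components, reg_epsilon)
    return model


def _solve_tica(
    C0: np.ndarray,
    Ct: np.ndarray,
    mean: np.ndarray,
    lag: int,
    labels: list[str],
    n_components: int | None,
    reg_epsilon: float,
) -> TICAModel:
    d = C0.shape[0]
    trace_scale = np.trace(C0) / d if d else 1.0
    rank_deficient = False
    eigvals_c0 = scipy.linalg.eigvalsh(C0)
    if eigvals_c0.min() < 1e-10 * max(eigvals_c0.max(), 1e-300):
        rank_deficient = True
        if reg_epsilon == 0:
            raise np.linalg.LinAlgError(
                "C0 is numerically singular; set reg_epsilon > 0"
            )
    C0r = C0 + np.eye(d) * (reg_epsilon * trace_scale)
    lam, V = scipy.linalg.eigh(Ct, C0r)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    if n_components is not None:
        lam, V = lam[:n_components], V[:, :n_components]
    # C0-metric normalization and deterministic sign: largest-|loading| positive
    for k in range(V.shape[1]):
        nrm = float(V[:, k] @ C0r @ V[:, k])
        if nrm > 0:
            V[:, k] /= np.sqrt(nrm)
        imax = int(np.argmax(np.abs(V[:, k])))
        if V[imax, k] < 0:
            V[:, k] = -V[:, k]
    return TICAModel(
        lag=lag,
        mean=mean,
        eigenvalues=lam,
        eigenvectors=V,
        labels=list(labels),
        rank_deficient=rank_deficient,
    )


def fit_tica_from_covariances(
    C0: np.ndarray,
    Ct: np.ndarray,
    mean: np.ndarray,
    lag: int,
    labels: list[str],
    n_components: int | None = None,
    reg_epsilon: float = 1e-6,
) -> TICAModel:
    """Fit from pre-accumulated covariances (used by the joint two-system fit)."""
    return _solve_tica(C0, Ct, mean, lag, labels, n_components, reg_epsilon)


def project(model: TICAModel, fm: FeatureMatrix) -> np.ndarray:
    """Project frames onto the tICs: (x − mean)·V.

    Features are matched to the model by label (order-insensitive).
    """
    if set(fm.labels) != set(model.labels):
        missing = sorted(set(model.labels) - set(fm.labels))
        extra = sorted(set(fm.labels) - set(model.labels))
        raise ValueError(f"feature label mismatch; missing={missing} extra={extra}")
    if fm.labels != model.labels:
        fm = fm.subset(model.labels)
    return (fm.values - model.mean) @ model.eigenvectors


def project_frame(model: TICAModel, values: np.ndarray, labels: list[str]) -> np.ndarray:
    """Project a single feature vector (used for reference structures)."""
    if labels != model.labels:
        pos = {lab: k for k, lab in enumerate(labels)}
        try:
            values = np.asarray([values[pos[lab]] for lab in model.labels])
        except KeyError as e:
            raise ValueError(f"missing feature {e} for projection") from e
    return (np.asarray(values, dtype=float) - model.mean) @ model.eigenvectors


def feature_tic_correlation(
    model: TICAModel, fm: FeatureMatrix, n_tics: int | None = None
) -> np.ndarray:
    """Pearson correlation of each raw feature with each projected tIC.

    Constant features get correlation 0 (flagged by the zero column std),
    never NaN.  Shape: (features, n_tics).
    """
    if n_tics is None:
        n_tics = model.n_components
    if n_tics > model.n_components:
        raise ValueError("n_tics exceeds model components")
    Y = project(model, fm)[:, :n_tics]
    X = fm.subset(model.labels).values if fm.labels != model.labels else fm.values
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = Yc.std(axis=0)
    sy[sy == 0] = np.inf
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ Yc) / X.shape[0] / np.outer(sx, sy)
    corr[sx == 0, :] = 0.0
    return np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
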