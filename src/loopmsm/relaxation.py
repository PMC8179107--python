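"""Backbone ¹⁵N relaxation analysis: R2/R1 classification and
Lipari–Szabo model-free fitting.

The spectral density is the standard two-timescale model-free form

    J(ω) = (2/5) [ S² τm / (1 + (ω τm)²) + (1 − S²) τ' / (1 + (ω τ')²) ],
    1/τ' = 1/τm + 1/τe,

with S² the generalized order parameter (1 = rigid N–H bond), τm the
global rotational correlation time (isotropic tumbling) and τe the
effective internal correlation time.  R1, R2 and the heteronuclear NOE
follow from dipolar (N–H, r = 1.02 Å) and ¹⁵N CSA (−172 ppm)
contributions evaluated at {0, ωN, ωH ± ωN, ωH}; chemical exchange adds
Rex to R2 only.

Qualitatively, the per-residue R2/R1 ratio tracks the apparent tumbling
time: residues above the ensemble mean + 1 SD report additional μs–ms
exchange (slow), residues below mean − 1 SD report large-amplitude ps–ns
motion (fast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "NucleusConstants",
    "RelaxationDataset",
    "ModelFreeResult",
    "R2R1Classification",
    "modelfree_forward",
    "estimate_tm",
    "modelfree_fit",
    "classify_r2r1",
]


@dataclass(frozen=True)
class NucleusConstants:
    """¹H–¹⁵N spin-pair constants (SI units)."""

    gamma_h: float = 2.6752218744e8   # rad s^-1 T^-1
    gamma_n: float = -2.7126e7        # rad s^-1 T^-1
    r_nh: float = 1.02e-10            # m
    csa: float = -172e-6              # ppm as fraction
    h_bar: float = 1.054571817e-34    # J s
    mu_0: float = 4e-7 * np.pi

    @property
    def dipolar(self) -> float:
        """d = (μ0/4π) ħ γH γN / r³  (rad/s)."""
        return (self.mu_0 / (4 * np.pi)) * self.h_bar * self.gamma_h * self.gamma_n / self.r_nh**3


DEFAULT_CONSTANTS = NucleusConstants()


@dataclass
class RelaxationDataset:
    """Per-residue R1, R2 (s⁻¹) and heteronuclear NOE with errors."""

    residue: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    NOE: np.ndarray
    R1_err: np.ndarray
    R2_err: np.ndarray
    NOE_err: np.ndarray
    field_MHz: float = 800.0
    constants: NucleusConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        for name in ("residue", "R1", "R2", "NOE", "R1_err", "R2_err", "NOE_err"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.R1 <= 0).any() or (self.R2 <= 0).any():
            raise ValueError("R1 and R2 must be positive")
        if (self.R1_err < 0).any() or (self.R2_err < 0).any() or (self.NOE_err < 0).any():
            raise ValueError("errors must be >= 0")
        if self.field_MHz <= 0:
            raise ValueError("field_MHz must be positive")

    @property
    def n_residues(self) -> int:
        return len(self.residue)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "residue": self.residue.astype(int),
                "R1": self.R1, "R1err": self.R1_err,
                "R2": self.R2, "R2err": self.R2_err,
                "NOE": self.NOE, "NOEerr": self.NOE_err,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, field_MHz: float = 800.0) -> "RelaxationDataset":
        df = pd.read_csv(path)
        return cls(
            residue=df["residue"], R1=df["R1"], R2=df["R2"], NOE=df["NOE"],
            R1_err=df["R1err"], R2_err=df["R2err"], NOE_err=df["NOEerr"],
            field_MHz=field_MHz,
        )


@dataclass
class ModelFreeResult:
    residue: np.ndarray
    S2: np.ndarray
    tau_e_ps: np.ndarray
    rex: np.ndarray
    model: list[str]             # "S2" | "S2+te" | "S2+te+Rex" | "failed"
    chi2: np.ndarray
    tau_m_ns: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue.astype(int),
                "S2": self.S2,
                "tau_e_ps": self.tau_e_ps,
                "Rex": self.rex,
                "model": self.model,
                "chi2": self.chi2,
            }
        )


@dataclass
class R2R1Classification:
    residue: np.ndarray
    ratio: np.ndarray
    mean: float
    sd: float
    classes: list[str]           # "slow" | "fast" | "typical"
    excluded: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residue.astype(int), "R2_R1": self.ratio,
             "class": self.classes}
        )


def _frequencies(field_MHz: float, c: NucleusConstants) -> tuple[float, float]:
    w_h = 2.0 * np.pi * field_MHz * 1e6
    w_n = w_h * c.gamma_n / c.gamma_h
    return w_h, w_n


def _spectral_density(w: float, S2: float, tau_m: float, tau_e: float) -> float:
    tm = tau_m
    if tau_e > 0:
        tp = 1.0 / (1.0 / tm + 1.0 / tau_e)
    else:
        tp = 0.0
    J = S2 * tm / (1.0 + (w * tm) ** 2)
    if tp > 0:
        J += (1.0 - S2) * tp / (1.0 + (w * tp) ** 2)
    return 0.4 * J  # 2/5 prefactor


def modelfree_forward(
    S2: float,
    tau_e_ps: float,
    tau_m_ns: float,
    rex: float = 0.0,
    field_MHz: float = 800.0,
    constants: NucleusConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """R1, R2 (s⁻¹) and ¹⁵N{¹H} NOE from model-free parameters.

    R1 = d²/4 [J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c² J(ωN)
    R2 = d²/8 [4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
         + c²/6 [4J(0) + 3J(ωN)] + Rex
    NOE = 1 + (γH/γN)(d²/4/R1)[6J(ωH+ωN) − J(ωH−ωN)]
    with d the dipolar coupling and c = ωN·CSA/√3.
    """
    if tau_m_ns <= 0:
        raise ValueError("tau_m must be positive")
    if not 0.0 <= S2 <= 1.0:
        raise ValueError("S2 must lie in [0, 1]")
    c = constants
    w_h, w_n = _frequencies(field_MHz, c)
    tau_m = tau_m_ns * 1e-9
    tau_e = tau_e_ps * 1e-12
    d2 = c.dipolar**2
    csa_c = w_n * c.csa / np.sqrt(3.0)
    c2 = csa_c**2

    def J(w: float) -> float:
        return _spectral_density(abs(w), S2, tau_m, tau_e)

    j0 = J(0.0)
    jn = J(w_n)
    jh = J(w_h)
    jhmn = J(w_h - w_n)
    jhpn = J(w_h + w_n)
    R1 = d2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    R2 = (
        d2 / 8.0 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
        + c2 / 6.0 * (4.0 * j0 + 3.0 * jn)
        + rex
    )
    NOE = 1.0 + (c.gamma_h / c.gamma_n) * (d2 / 4.0 / R1) * (6.0 * jhpn - jhmn)
    return float(R1), float(R2), float(NOE)


def _rigid_r2_over_r1(tau_m_ns: float, field_MHz: float,
                      constants: NucleusConstants) -> float:
    r1, r2, _ = modelfree_forward(1.0, 0.0, tau_m_ns, 0.0, field_MHz, constants)
    return r2 / r1


def estimate_tm(
    dataset: RelaxationDataset,
    noe_cutoff: float = 0.65,
    tau_bounds_ns: tuple[float, float] = (0.5, 60.0),
    min_residues: int = 5,
) -> float:
    """Isotropic rotational correlation time from trimmed R2/R1 ratios.

    Residues with R2/R1 outside mean ± 1 SD (likely exchange-broadened or
    highly flexible) or with NOE below ``noe_cutoff`` (mobile) are
    excluded; for each retained residue the rigid-limit R2/R1(τm)
    relation is inverted numerically, and the median τm is returned.
    """
    ratio = dataset.R2 / dataset.R1
    mean, sd = float(ratio.mean()), float(ratio.std(ddof=0))
    keep = np.abs(ratio - mean) <= sd
    keep &= dataset.NOE >= noe_cutoff
    if keep.sum() < min_residues:
        raise ValueError(
            f"only {int(keep.sum())} residues retained after trimming; "
            f"need >= {min_residues}"
        )
    lo, hi = tau_bounds_ns
    taus = []
    for r in ratio[keep]:
        f = lambda tm: _rigid_r2_over_r1(tm, dataset.field_MHz, dataset.constants) - r
        try:
            taus.append(brentq(f, lo, hi, xtol=1e-6))
        except ValueError:
            continue
    if len(taus) < min_residues:
        raise ValueError("too few residues admitted a tau_m solution in bounds")
    return float(np.median(taus))


_MODELS = {
    "S2": ("S2",),
    "S2+te": ("S2", "te"),
    "S2+te+Rex": ("S2", "te", "Rex"),
}


def _fit_one(
    obs: np.ndarray,
    err: np.ndarray,
    tau_m_ns: float,
    field_MHz: float,
    constants: NucleusConstants,
    params: tuple[str, ...],
) -> tuple[np.ndarray, float]:
    """Weighted LS fit of one residue under one model; returns (x, chi2)."""

    def unpack(x):
        s2 = x[0]
        te = x[1] if "te" in params else 0.0
        rex = x[2] if "Rex" in params else 0.0
        return s2, te, rex

    def resid(x):
        s2, te, rex = unpack(x)
        r1, r2, noe = modelfree_forward(s2, te, tau_m_ns, rex, field_MHz, constants)
        return (np.array([r1, r2, noe]) - obs) / err

    lower = [0.0]
    upper = [1.0]
    x0s = [[0.85]]
    if "te" in params:
        lower.append(0.0)
        upper.append(min(tau_m_ns * 1e3 * 0.5, 5000.0))
        x0s = [[0.85, 30.0], [0.6, 300.0], [0.95, 5.0]]
    if "Rex" in params:
        lower.append(0.0)
        upper.append(50.0)
        x0s = [x + [0.0] for x in x0s] + [[0.85, 30.0, 5.0]]
    best, best_chi2 = None, np.inf
    for x0 in x0s:
        try:
            sol = least_squares(
                resid, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14,
                gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        chi2 = float(np.sum(sol.fun**2))
        if chi2 < best_chi2:
            best, best_chi2 = sol.x, chi2
    if best is None:
        raise RuntimeError("optimizer failed for all starts")
    return best, best_chi2


def modelfree_fit(
    dataset: RelaxationDataset,
    tau_m_ns: float | None = None,
    delta_chi2: float = 4.6,
) -> ModelFreeResult:
    """Per-residue model-free fit at fixed τm with nested model selection.

    Candidate models: S² only; S² + τe; S² + τe + Rex.  The simplest model
    is kept unless the next one improves χ² by more than ``delta_chi2``.
    Residues whose optimizer fails are flagged "failed" and skipped.
    """
    if tau_m_ns is None:
        tau_m_ns = estimate_tm(dataset)
    n = dataset.n_residues
    S2 = np.full(n, np.nan)
    te = np.full(n, np.nan)
    rex = np.full(n, np.nan)
    chi2_out = np.full(n, np.nan)
    models: list[str] = []
    for k in range(n):
        obs = np.array([dataset.R1[k], dataset.R2[k], dataset.NOE[k]])
        err = np.array([
            max(dataset.R1_err[k], 1e-8),
            max(dataset.R2_err[k], 1e-8),
            max(dataset.NOE_err[k], 1e-8),
        ])
        fits = {}
        try:
            for name, params in _MODELS.items():
                fits[name] = _fit_one(
                    obs, err, tau_m_ns, dataset.field_MHz, dataset.constants, params
                )
        except RuntimeError:
            models.append("failed")
            continue
        chosen = "S2"
        if fits["S2"][1] - fits["S2+te"][1] > delta_chi2:
            chosen = "S2+te"
        if fits[chosen][1] - fits["S2+te+Rex"][1] > delta_chi2:
            chosen = "S2+te+Rex"
        x, c2 = fits[chosen]
        S2[k] = x[0]
        te[k] = x[1] if len(x) > 1 else 0.0
        rex[k] = x[2] if len(x) > 2 else 0.0
        chi2_out[k] = c2
        models.append(chosen)
    return ModelFreeResult(
        residue=dataset.residue, S2=S2, tau_e_ps=te, rex=rex,
        model=models, chi2=chi2_out, tau_m_ns=tau_m_ns,
    )


def classify_r2r1(dataset: RelaxationDataset) -> R2R1Classification:
    """Three-way R2/R1 classification against the ensemble mean ± 1 SD.

    slow (μs–ms exchange): ratio > mean + 1 SD; fast (ps–ns flexibility):
    ratio < mean − 1 SD; typical otherwise.  Residues missing either rate
    (NaN) are excluded and listed.
    """
    ok = np.isfinite(dataset.R1) & np.isfinite(dataset.R2)
    if ok.sum() < 3:
        raise ValueError("need at least 3 residues with both R1 and R2")
    ratio = np.where(ok, dataset.R2 / np.where(ok, dataset.R1, 1.0), np.nan)
    mean = float(np.nanmean(ratio))
    sd = float(np.nanstd(ratio, ddof=0))
    classes = []
    for k in range(dataset.n_residues):
        if not ok[k]:
            classes.append("excluded")
        elif ratio[k] > mean + sd:
            classes.append("slow")
        elif ratio[k] < mean - sd:
            classes.append("fast")
        else:
            classes.append("typical")
    return R2R1Classification(
        residue=dataset.residue,
        ratio=ratio,
        mean=mean,
        sd=sd,
        classes=classes,
        excluded=[int(dataset.residue[k]) for k in np.where(~ok)[0]],
    )
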