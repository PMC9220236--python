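"""Analytic linear mammillary compartment models with zero-order IV infusion.

One-, two-, and three-compartment models with elimination from the central
compartment, parameterised by clearances and volumes (CL, V1, Q1, V2, Q2, V3).
Concentration-time profiles are computed from the eigendecomposition of the
first-order rate matrix, which is exact for linear kinetics and cheap enough
to evaluate inside an estimation loop.  Amounts are propagated; concentration
is the central amount divided by V1.

Micro-constant convention: k10 = CL/V1, k12 = Q1/V1, k21 = Q1/V2,
k13 = Q2/V1, k31 = Q2/V3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "StructuralParams",
    "Regimen",
    "ExposureMetrics",
    "PARAM_NAMES",
    "concentration_single_dose",
    "concentration_steady_state",
    "vss",
    "steady_state_exposure",
    "conc_single_matrix",
    "conc_steady_state_matrix",
    "steady_state_exposure_matrix",
]

#: Structural parameter column order for each model order (matrix interfaces).
PARAM_NAMES = {
    1: ("CL", "V1"),
    2: ("CL", "V1", "Q1", "V2"),
    3: ("CL", "V1", "Q1", "V2", "Q2", "V3"),
}

#: Grid step (h) used to locate the steady-state concentration maximum.
CMAX_GRID_STEP = 0.01


class InvalidParameterError(ValueError):
    """A structural parameter or regimen field violates its constraints."""


@dataclass(frozen=True)
class StructuralParams:
    """Structural parameters of a 1/2/3-compartment mammillary model.

    Clearances in L/h, volumes in L.  Only the fields implied by
    ``n_compartments`` may be set: (CL, V1) for one compartment, plus
    (Q1, V2) for two, plus (Q2, V3) for three.
    """

    n_compartments: int
    CL: float
    V1: float
    Q1: float | None = None
    V2: float | None = None
    Q2: float | None = None
    V3: float | None = None

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise InvalidParameterError(
                f"n_compartments must be 1, 2 or 3, got {self.n_compartments}"
            )
        names = PARAM_NAMES[self.n_compartments]
        for name in ("CL", "V1", "Q1", "V2", "Q2", "V3"):
            value = getattr(self, name)
            if name in names:
                if value is None or not np.isfinite(value) or value <= 0:
                    raise InvalidParameterError(
                        f"{name} must be strictly positive for a "
                        f"{self.n_compartments}-compartment model, got {value}"
                    )
            elif value is not None:
                raise InvalidParameterError(
                    f"{name} is not a parameter of a "
                    f"{self.n_compartments}-compartment model"
                )

    def to_vector(self) -> np.ndarray:
        """Parameter values in the canonical ``PARAM_NAMES`` column order."""
        return np.array(
            [getattr(self, name) for name in PARAM_NAMES[self.n_compartments]],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, n_compartments: int, values) -> "StructuralParams":
        names = PARAM_NAMES[n_compartments]
        if len(values) != len(names):
            raise InvalidParameterError(
                f"expected {len(names)} values for a {n_compartments}-compartment "
                f"model, got {len(values)}"
            )
        return cls(n_compartments, **dict(zip(names, map(float, values))))


@dataclass(frozen=True)
class Regimen:
    """Intermittent IV infusion regimen.

    dose in mg per administration, infusion_duration and interval (tau) in h.
    ``n_doses`` is a positive integer or the string ``"steady_state"``.
    """

    dose: float
    infusion_duration: float
    interval: float
    n_doses: Union[int, str] = "steady_state"

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise InvalidParameterError(f"dose must be positive, got {self.dose}")
        if not 0 < self.infusion_duration <= self.interval:
            raise InvalidParameterError(
                "require 0 < infusion_duration <= interval, got "
                f"{self.infusion_duration} and {self.interval}"
            )
        if self.n_doses != "steady_state" and (
            not isinstance(self.n_doses, int) or self.n_doses < 1
        ):
            raise InvalidParameterError(f"invalid n_doses: {self.n_doses!r}")

    @property
    def rate(self) -> float:
        """Zero-order infusion rate, mg/h."""
        return self.dose / self.infusion_duration


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure for one individual: AUC over 24 h (mg*h/L),
    peak (Cmax) and pre-dose trough (Cmin) concentrations (mg/L)."""

    auc24: float
    cmax: float
    cmin: float


# ---------------------------------------------------------------------------
# Eigendecomposition of the rate matrix
# ---------------------------------------------------------------------------

def _modes(n_cmt: int, P: np.ndarray):
    """Eigen-modes of the amount rate matrix for a batch of parameter sets.

    P has shape (n, k) with columns in PARAM_NAMES order.  Returns
    (lam, amp): eigenvalues lam (n, m) and central-compartment amplitudes
    amp (n, m) for a unit zero-order input into the central compartment,
    i.e. the central amount is sum_k amp_k * (mode_k response).  The rate
    matrix of a mammillary model is symmetrisable by the volume scaling
    D = diag(1/sqrt(V)), so its eigenvalues are real; in the symmetrised
    basis the amplitude reduces to the squared first eigenvector component.
    The two-compartment case uses the closed-form quadratic roots.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    n = P.shape[0]
    CL, V1 = P[:, 0], P[:, 1]

    if n_cmt == 1:
        return (-CL / V1)[:, None], np.ones((n, 1))

    if n_cmt == 2:
        Q1, V2 = P[:, 2], P[:, 3]
        a = -(CL + Q1) / V1
        dd = -Q1 / V2
        tr = a + dd
        det = a * dd - (Q1 / V2) * (Q1 / V1)
        disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
        lam1 = 0.5 * (tr - disc)
        lam2 = 0.5 * (tr + disc)
        gap = np.maximum(lam2 - lam1, 1e-300)
        amp = np.stack([(lam2 - a) / gap, (a - lam1) / gap], axis=1)
        return np.stack([lam1, lam2], axis=1), amp

    Q1, V2, Q2, V3 = P[:, 2], P[:, 3], P[:, 4], P[:, 5]
    vols = np.stack([V1, V2, V3], axis=1)
    A = np.zeros((n, 3, 3))
    A[:, 0, 0] = -(CL + Q1 + Q2) / V1
    A[:, 0, 1] = Q1 / V2
    A[:, 1, 0] = Q1 / V1
    A[:, 1, 1] = -Q1 / V2
    A[:, 0, 2] = Q2 / V3
    A[:, 2, 0] = Q2 / V1
    A[:, 2, 2] = -Q2 / V3
    # Similarity transform B = D A D^-1 with D = diag(1/sqrt(V)) is symmetric.
    d = 1.0 / np.sqrt(vols)
    B = A * (d[:, :, None] / d[:, None, :])
    lam, U = np.linalg.eigh(B)
    return lam, U[:, 0, :] ** 2


def _h_infusion(lam: np.ndarray, s: np.ndarray) -> np.ndarray:
    """(exp(lam*s) - 1)/lam, stable for small |lam*s|."""
    # expm1(lam*s)/lam -> s smoothly as lam*s -> 0; lam < 0 always (CL > 0),
    # so the only guard needed is against an exactly-zero eigenvalue.
    lam = np.where(lam == 0.0, -1e-300, lam)
    return np.expm1(lam * s) / lam


def conc_single_matrix(
    n_cmt: int, P: np.ndarray, dose: float, dur: float, t: np.ndarray
) -> np.ndarray:
    """Single-dose central concentration for a batch of parameter sets.

    P: (n, k) parameter matrix; t: (T,) times in h.  Returns (n, T) mg/L.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lam, amp = _modes(n_cmt, P)
    rate = dose / dur
    coef = amp * rate / P[:, 1, None]                    # (n, m)
    s = np.minimum(t, dur)                               # (T,)
    decay = np.maximum(t - dur, 0.0)
    lamT = lam[:, :, None]                               # (n, m, 1)
    modes = np.exp(lamT * decay) * _h_infusion(lamT, s)  # (n, m, T)
    return np.einsum("nm,nmt->nt", coef, modes)


def conc_steady_state_matrix(
    n_cmt: int, P: np.ndarray, dose: float, dur: float, tau: float, t: np.ndarray
) -> np.ndarray:
    """Periodic steady-state central concentration within one dosing interval.

    The pre-dose state is the fixed point of the one-interval map, solved in
    closed form in the eigenbasis: each mode accumulates by the geometric
    factor 1/(1 - exp(lam*tau)).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lam, amp = _modes(n_cmt, P)
    rate = dose / dur
    coef = amp * rate / P[:, 1, None]
    s = np.minimum(t, dur)
    decay = np.maximum(t - dur, 0.0)
    lamT = lam[:, :, None]
    single = np.exp(lamT * decay) * _h_infusion(lamT, s)
    # residue of the previous doses, decayed through the current interval
    accum = np.exp(lam * (tau - dur)) * _h_infusion(lam, np.full_like(lam, dur))
    accum = accum / -np.expm1(lam * tau)                 # (n, m)
    modes = single + accum[:, :, None] * np.exp(lamT * t)
    return np.einsum("nm,nmt->nt", coef, modes)


def steady_state_exposure_matrix(
    n_cmt: int,
    P: np.ndarray,
    regimen: Regimen,
    grid_step: float = CMAX_GRID_STEP,
    chunk: int = 1000,
) -> dict[str, np.ndarray]:
    """Vectorised steady-state exposure (auc24, cmax, cmin) for a batch.

    auc24 uses the exact linear-PK identity (24/tau) * dose / CL; cmax is the
    maximum of the steady-state profile on a grid with step ``grid_step``;
    cmin is the concentration at t = tau (pre-dose trough).  Evaluation is
    chunked to bound memory for large populations.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    tau = regimen.interval
    auc24 = (24.0 / tau) * regimen.dose / P[:, 0]
    grid = np.arange(0.0, tau + grid_step / 2, grid_step)
    cmax = np.empty(P.shape[0])
    cmin = np.empty(P.shape[0])
    for start in range(0, P.shape[0], chunk):
        block = slice(start, start + chunk)
        prof = conc_steady_state_matrix(
            n_cmt, P[block], regimen.dose, regimen.infusion_duration, tau, grid
        )
        cmax[block] = prof.max(axis=1)
        cmin[block] = prof[:, -1]
    return {"auc24": auc24, "cmax": cmax, "cmin": cmin}


# ---------------------------------------------------------------------------
# Scalar (single-individual) interface
# ---------------------------------------------------------------------------

def concentration_single_dose(p: StructuralParams, r: Regimen, t):
    """Central concentration (mg/L) after a single zero-order infusion.

    ``t`` may be a scalar or array of times (h) from the start of infusion.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise InvalidParameterError("time must be non-negative")
    out = conc_single_matrix(
        p.n_compartments, p.to_vector(), r.dose, r.infusion_duration, t_arr
    )[0]
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def concentration_steady_state(p: StructuralParams, r: Regimen, t_in_interval):
    """Steady-state central concentration (mg/L) at a time within one interval."""
    t_arr = np.atleast_1d(np.asarray(t_in_interval, dtype=float))
    if np.any(t_arr < 0) or np.any(t_arr > r.interval):
        raise InvalidParameterError("t_in_interval must lie in [0, interval]")
    out = conc_steady_state_matrix(
        p.n_compartments,
        p.to_vector(),
        r.dose,
        r.infusion_duration,
        r.interval,
        t_arr,
    )[0]
    if np.isscalar(t_in_interval) or np.ndim(t_in_interval) == 0:
        return float(out[0])
    return out


def vss(p: StructuralParams) -> float:
    """Steady-state volume of distribution: the sum of all compartment volumes."""
    return float(sum(v for v in (p.V1, p.V2, p.V3) if v is not None))


def steady_state_exposure(
    p: StructuralParams, r: Regimen, grid_step: float = CMAX_GRID_STEP
) -> ExposureMetrics:
    """Steady-state AUC24, Cmax and Cmin for one individual under a regimen."""
    res = steady_state_exposure_matrix(
        p.n_compartments, p.to_vector(), r, grid_step=grid_step
    )
    return ExposureMetrics(
        auc24=float(res["auc24"][0]),
        cmax=float(res["cmax"][0]),
        cmin=float(res["cmin"][0]),
    )
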