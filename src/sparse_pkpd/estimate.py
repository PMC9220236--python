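"""Nonlinear mixed-effects estimation by FOCE with eta-eps interaction.

Fits 1/2/3-compartment infusion models to single-dose concentration datasets.
Random effects are diagonal log-normal on a subset of the structural
parameters; the residual model is proportional.  For each subject the
conditional mode eta-hat minimises

    sum_j [ ln(sigma^2 f_j(eta)^2) + (y_j - f_j(eta))^2 / (sigma^2 f_j(eta)^2) ]
        + eta' Omega^-1 eta,

and the population objective is the FOCE-I approximation to -2 log marginal
likelihood: the model is linearised around eta-hat, giving per subject

    ln det C + (y - f(eta-hat) + J eta-hat)' C^-1 (y - f(eta-hat) + J eta-hat)
        + n_obs ln 2*pi,     C = J Omega J' + diag(sigma^2 f(eta-hat)^2),

with the residual variance evaluated at the conditional mode (interaction).
The outer problem is solved by quasi-Newton (L-BFGS-B) on the logs of the
fixed effects, random-effect variances and residual variance, with jittered
restarts on failure.  Inner problems are solved for all subjects at once by a
damped Gauss-Newton iteration, warm-started across outer iterations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .pk_core import PARAM_NAMES, StructuralParams, conc_single_matrix

__all__ = [
    "ModelSpec",
    "FitResult",
    "DesignInsufficientError",
    "individual_map_eta",
    "foce_objective",
    "fit",
    "empirical_bayes_params",
]

logger = logging.getLogger(__name__)

#: Default diagonal random-effect structure per fitted model order: the
#: minimal structure consistent with the generating models (clearance and
#: volumes carry BSV; intercompartmental clearances do not).
DEFAULT_RANDOM_EFFECTS = {
    1: ("CL", "V1"),
    2: ("CL", "V1"),
    3: ("CL", "V1", "V2", "V3"),
}

_F_FLOOR = 1e-10          # floor on model predictions inside variance terms
_PENALTY = 1e12           # objective value returned on numerical failure
_INNER_TOL = 1e-6         # inner Gauss-Newton step tolerance
_INNER_GTOL = 1e-5        # inner gradient-norm stopping tolerance
_INNER_MAX_ITER = 30
_FD_ETA = 1e-5            # forward-difference step for d f / d eta
_OUTER_MAX_ITER = 500
_N_RESTARTS = 5


class DesignInsufficientError(ValueError):
    """The sampling design cannot identify the requested model order."""


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: compartments, random-effect set, error model."""

    n_compartments: int
    random_effect_params: tuple[str, ...] = ()
    error_model: str = "proportional"

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise ValueError("n_compartments must be 1, 2 or 3")
        if self.error_model != "proportional":
            raise ValueError("only the proportional error model is supported")
        if not self.random_effect_params:
            object.__setattr__(
                self,
                "random_effect_params",
                DEFAULT_RANDOM_EFFECTS[self.n_compartments],
            )
        names = PARAM_NAMES[self.n_compartments]
        bad = [p for p in self.random_effect_params if p not in names]
        if bad:
            raise ValueError(f"random effects on unknown parameters: {bad}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.n_compartments]

    @property
    def re_indices(self) -> np.ndarray:
        names = self.param_names
        return np.array([names.index(p) for p in self.random_effect_params])


@dataclass
class FitResult:
    """Population fit: fixed effects, variances, objective, and EBEs.

    ``theta`` maps structural parameter names to estimates; ``omega`` maps
    random-effect parameter names to log-scale variances (omega^2);
    ``sigma`` is the proportional residual variance (sigma^2).  ``ebe``
    holds one StructuralParams per subject built from theta and the
    empirical Bayes eta-hat.
    """

    spec: ModelSpec
    theta: dict[str, float]
    omega: dict[str, float]
    sigma: float
    ofv: float
    converged: bool
    ebe: list[StructuralParams]
    eta: np.ndarray
    subject_ids: list = field(default_factory=list)
    ofv_trace: list = field(default_factory=list)
    n_restarts_used: int = 0

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[p] for p in self.spec.param_names])

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "n_compartments": self.spec.n_compartments,
            "theta": self.theta,
            "omega": self.omega,
            "sigma": self.sigma,
            "ofv": self.ofv,
            "converged": self.converged,
            "n_subjects": len(self.ebe),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    def ebe_frame(self) -> pd.DataFrame:
        rows = [
            {"ID": sid, **{p: getattr(e, p) for p in self.spec.param_names}}
            for sid, e in zip(self.subject_ids, self.ebe)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dataset -> rectangular arrays
# ---------------------------------------------------------------------------

def _extract_arrays(dataset: pd.DataFrame):
    """Pull (subject_ids, times, y, mask, dose, duration) from a dataset.

    Observations are records with EVID=0 and MDV=0.  All subjects are
    expected to share one dosing regimen; observation times may differ per
    subject (mask marks missing cells).
    """
    doses = dataset[dataset["EVID"] == 1]
    if doses.empty:
        raise ValueError("dataset contains no dose records")
    dose = float(doses["AMT"].iloc[0])
    rate = float(doses["RATE"].iloc[0])
    if not (np.allclose(doses["AMT"], dose) and np.allclose(doses["RATE"], rate)):
        raise ValueError("all subjects must share one dosing regimen")
    dur = dose / rate

    obs = dataset[(dataset["EVID"] == 0) & (dataset["MDV"] == 0)]
    if obs.empty:
        raise ValueError("dataset contains no usable observations")
    subject_ids = sorted(dataset.loc[dataset["EVID"] == 1, "ID"].unique())
    times = np.array(sorted(obs["TIME"].unique()), dtype=float)
    t_index = {t: j for j, t in enumerate(times)}
    n, T = len(subject_ids), len(times)
    y = np.zeros((n, T))
    mask = np.zeros((n, T))
    id_index = {s: i for i, s in enumerate(subject_ids)}
    for sid, t, dv in zip(obs["ID"], obs["TIME"], obs["DV"]):
        y[id_index[sid], t_index[t]] = dv
        mask[id_index[sid], t_index[t]] = 1.0
    return subject_ids, times, y, mask, dose, dur


def _check_identifiable(spec: ModelSpec, times: np.ndarray) -> None:
    needed = len(spec.param_names)
    if len(times) < needed:
        raise DesignInsufficientError(
            f"a {spec.n_compartments}-compartment model has {needed} structural "
            f"parameters but the design provides only {len(times)} distinct "
            "usable observation times"
        )


# ---------------------------------------------------------------------------
# Inner problem: conditional modes for all subjects at once
# ---------------------------------------------------------------------------

class _FOCEProblem:
    """Rectangular FOCE-I problem with vectorised inner optimisation."""

    def __init__(self, spec: ModelSpec, dataset: pd.DataFrame):
        self.spec = spec
        (self.subject_ids, self.times, self.y, self.mask,
         self.dose, self.dur) = _extract_arrays(dataset)
        _check_identifiable(spec, self.times)
        self.n = self.y.shape[0]
        self.d = len(spec.random_effect_params)
        self.re_idx = spec.re_indices
        self.eta = np.zeros((self.n, self.d))  # warm start across calls

    # -- model predictions ---------------------------------------------------
    def _predict(self, theta: np.ndarray, eta: np.ndarray) -> np.ndarray:
        P = np.tile(theta, (self.n, 1))
        P[:, self.re_idx] *= np.exp(eta)
        return conc_single_matrix(
            self.spec.n_compartments, P, self.dose, self.dur, self.times
        )

    def _predict_with_jac(self, theta, eta):
        f = self._predict(theta, eta)
        J = np.empty((self.n, self.y.shape[1], self.d))
        for k in range(self.d):
            step = np.zeros_like(eta)
            step[:, k] = _FD_ETA
            J[:, :, k] = (self._predict(theta, eta + step) - f) / _FD_ETA
        return f, J

    # -- inner objective -----------------------------------------------------
    def _inner_value(self, eta, theta, omega2, sigma2) -> np.ndarray:
        f = np.maximum(self._predict(theta, eta), _F_FLOOR)
        g2 = sigma2 * f**2
        r = self.y - f
        terms = self.mask * (np.log(g2) + r**2 / g2)
        return terms.sum(axis=1) + (eta**2 / omega2).sum(axis=1)

    def solve_inner(self, theta, omega2, sigma2, eta0=None,
                    tol=_INNER_TOL, max_iter=_INNER_MAX_ITER):
        """Damped Gauss-Newton for all subjects' conditional modes."""
        eta = np.zeros((self.n, self.d)) if eta0 is None else eta0.copy()
        value = self._inner_value(eta, theta, omega2, sigma2)
        inv_omega2 = 1.0 / omega2
        eye = np.eye(self.d)
        for _ in range(max_iter):
            f, J = self._predict_with_jac(theta, eta)
            f = np.maximum(f, _F_FLOOR)
            g2 = sigma2 * f**2
            r = self.y - f
            dh_df = self.mask * (2.0 / f - 2.0 * r / g2 - 2.0 * r**2 / (g2 * f))
            grad = np.einsum("nt,ntk->nk", dh_df, J) + 2.0 * eta * inv_omega2
            if np.abs(grad).max() < _INNER_GTOL:
                break
            # full d2h/df2 (clipped to stay positive definite); the neglected
            # d2f/deta2 term keeps this a Gauss-Newton-type iteration
            d2h = (
                -2.0 / f**2
                + 2.0 / g2
                + 8.0 * r / (g2 * f)
                + 6.0 * r**2 / (g2 * f**2)
            )
            w = self.mask * np.maximum(d2h, 0.2 / g2)
            H = np.einsum("nt,ntk,ntl->nkl", w, J, J) + 2.0 * np.diag(inv_omega2)
            H = H + 1e-10 * eye
            try:
                step = -np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = -grad / np.maximum(np.einsum("nkk->nk", H), 1e-6)
            step = np.clip(step, -5.0, 5.0)  # single-step cap; |eta| stays sane
            # vectorised backtracking: halve the step where it does not improve
            scale = np.ones(self.n)
            improved = np.zeros(self.n, dtype=bool)
            new_eta = eta.copy()
            new_value = value.copy()
            for _bt in range(6):
                trial = np.clip(eta + scale[:, None] * step, -20.0, 20.0)
                tv = self._inner_value(trial, theta, omega2, sigma2)
                better = (tv < new_value) & ~improved
                new_eta[better] = trial[better]
                new_value[better] = tv[better]
                improved |= better
                if improved.all():
                    break
                scale[~improved] *= 0.5
            applied = np.abs(new_eta - eta).max() if improved.any() else 0.0
            gain = (value - new_value).max() if improved.any() else 0.0
            eta, value = new_eta, new_value
            if applied < tol or gain < 1e-10:
                break
        return eta

    # -- FOCE-I objective ----------------------------------------------------
    def objective(self, theta, omega2, sigma2, warm=True, update_warm=True) -> float:
        """FOCE-I -2 log-likelihood approximation at a population parameter set.

        ``warm`` starts the inner solve from the stored conditional modes;
        ``update_warm=False`` leaves the stored modes untouched so repeated
        evaluations (finite differences, line searches) see a consistent
        objective surface.
        """
        eta0 = self.eta if warm else None
        eta = self.solve_inner(theta, omega2, sigma2, eta0=eta0)
        if update_warm:
            self.eta = eta
        f, J = self._predict_with_jac(theta, eta)
        f = np.maximum(f, _F_FLOOR)
        g2 = sigma2 * f**2
        # masked covariance: unobserved rows/cols replaced by identity
        Om = np.diag(omega2)
        C = np.einsum("ntk,kl,nsl->nts", J, Om, J)
        C = C * (self.mask[:, :, None] * self.mask[:, None, :])
        T = self.y.shape[1]
        idx = np.arange(T)
        C[:, idx, idx] += self.mask * g2 + (1.0 - self.mask)
        res = (self.y - f + np.einsum("ntk,nk->nt", J, eta)) * self.mask
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return _PENALTY
        logdet = 2.0 * np.log(np.einsum("ntt->nt", L)).sum()
        z = np.linalg.solve(L, res[:, :, None])[:, :, 0]
        quad = (z**2).sum()
        n_obs = self.mask.sum()
        ofv = logdet + quad + n_obs * np.log(2.0 * np.pi)
        # unobserved cells contributed ln(1)+0 to logdet/quad: nothing to remove
        if not np.isfinite(ofv):
            return _PENALTY
        return float(ofv)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _as_vectors(spec: ModelSpec, theta, omega, sigma2):
    names = spec.param_names
    th = (
        np.array([theta[p] for p in names], dtype=float)
        if isinstance(theta, dict)
        else np.asarray(theta, dtype=float)
    )
    om = (
        np.array([omega[p] for p in spec.random_effect_params], dtype=float)
        if isinstance(omega, dict)
        else np.asarray(omega, dtype=float)
    )
    if th.shape != (len(names),) or om.shape != (len(spec.random_effect_params),):
        raise ValueError("theta/omega have the wrong length for this spec")
    if np.any(th <= 0) or np.any(om <= 0) or sigma2 <= 0:
        raise ValueError("theta, omega^2 and sigma^2 must be positive")
    return th, om, float(sigma2)


def individual_map_eta(
    spec: ModelSpec, theta, omega, sigma2, subject_records: pd.DataFrame
) -> np.ndarray:
    """Conditional mode eta-hat for a single subject's records.

    ``omega`` holds the random-effect variances (omega^2) and ``sigma2``
    the proportional residual variance.  On inner non-convergence the
    zero vector is returned with a warning.
    """
    th, om, s2 = _as_vectors(spec, theta, omega, sigma2)
    problem = _FOCEProblem(spec, subject_records)
    try:
        eta = problem.solve_inner(th, om, s2)
    except Exception:  # pragma: no cover - defensive
        logger.warning("inner eta optimisation failed; returning eta=0")
        return np.zeros(len(spec.random_effect_params))
    return eta[0] if eta.shape[0] == 1 else eta


def foce_objective(spec: ModelSpec, theta, omega, sigma2, dataset: pd.DataFrame) -> float:
    """FOCE-I approximate -2 log marginal likelihood of a dataset."""
    th, om, s2 = _as_vectors(spec, theta, omega, sigma2)
    problem = _FOCEProblem(spec, dataset)
    return problem.objective(th, om, s2, warm=False)


def _initial_estimates(problem: _FOCEProblem) -> np.ndarray:
    """Heuristic initial structural estimates from the pooled mean profile.

    CL from dose / trapezoidal AUC of the mean profile (with log-linear tail
    extrapolation), V from dose / peak mean concentration, peripheral
    compartments seeded as fractions of V.
    """
    counts = problem.mask.sum(axis=0)
    mean_y = np.where(counts > 0, problem.y.sum(axis=0) / np.maximum(counts, 1), np.nan)
    t = problem.times
    ok = np.isfinite(mean_y) & (mean_y > 0)
    t, mean_y = t[ok], mean_y[ok]
    auc = np.trapezoid(np.concatenate([[0.0], mean_y]), np.concatenate([[0.0], t]))
    if len(t) >= 2 and mean_y[-1] < mean_y[-2]:
        kz = np.log(mean_y[-2] / mean_y[-1]) / (t[-1] - t[-2])
        auc += mean_y[-1] / kz
    else:
        auc *= 1.5
    cl0 = problem.dose / max(auc, 1e-6)
    v0 = problem.dose / max(mean_y.max(), 1e-6)
    n_cmt = problem.spec.n_compartments
    if n_cmt == 1:
        return np.array([cl0, v0])
    if n_cmt == 2:
        return np.array([cl0, 0.5 * v0, cl0, 0.75 * v0])
    return np.array([cl0, v0 / 3, cl0, v0 / 2, cl0, v0 / 3])


def fit(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    inits: np.ndarray | dict | None = None,
    rng_seed: int = 0,
) -> FitResult:
    """Fit a population model to a dataset by FOCE-I.

    The outer optimisation runs on log(theta), log(omega^2), log(sigma^2)
    (positivity by construction) with up to five jittered restarts on
    failure.  Raises DesignInsufficientError when the design has fewer
    distinct usable times than the model has structural parameters.
    """
    problem = _FOCEProblem(spec, dataset)
    k, d = len(spec.param_names), problem.d

    if inits is None:
        theta0 = _initial_estimates(problem)
    elif isinstance(inits, dict):
        theta0 = np.array([inits[p] for p in spec.param_names], dtype=float)
    else:
        theta0 = np.asarray(inits, dtype=float)
    omega0 = np.full(d, 0.1)
    sigma0 = 0.02
    x0 = np.log(np.concatenate([theta0, omega0, [sigma0]]))

    trace: list[float] = []

    def unpack(x):
        return np.exp(x[:k]), np.exp(x[k:k + d]), float(np.exp(x[-1]))

    # Optimise the per-observation objective so the log-space gradient is
    # O(1) and the quasi-Newton line search starts at a sensible step size.
    n_obs = max(problem.mask.sum(), 1.0)

    def objective(x):
        th, om, s2 = unpack(x)
        try:
            value = problem.objective(th, om, s2, update_warm=False)
        except Exception:
            return _PENALTY
        return min(value, _PENALTY) / n_obs

    def on_iterate(xk):
        # refresh the shared warm start once per accepted outer iterate
        th, om, s2 = unpack(xk)
        try:
            trace.append(problem.objective(th, om, s2))
        except Exception:
            trace.append(float("nan"))

    bounds = [(-12.0, 12.0)] * (k + d + 1)
    rng = np.random.default_rng(rng_seed)
    best = None
    n_restarts_used = 0
    start = x0
    for attempt in range(_N_RESTARTS + 1):
        problem.eta = np.zeros((problem.n, d))
        res = minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            callback=on_iterate,
            options={
                "maxiter": _OUTER_MAX_ITER,
                "ftol": 5e-10,
                "gtol": 1e-7,
                "eps": 1e-5,
                "maxls": 40,
            },
        )
        ok = bool(res.success) and np.isfinite(res.fun) and res.fun * n_obs < _PENALTY / 2
        if best is None or res.fun < best.fun:
            best = res
        if ok:
            break
        n_restarts_used = attempt + 1
        start = x0 + rng.normal(0.0, 0.3, x0.shape)
        logger.warning(
            "fit restart %d (status=%s, fun=%.4g)", attempt + 1, res.status, res.fun
        )

    theta, omega2, sigma2 = unpack(best.x)
    problem.eta = np.zeros((problem.n, d))
    ofv = problem.objective(theta, omega2, sigma2)
    eta = problem.eta
    P = np.tile(theta, (problem.n, 1))
    P[:, problem.re_idx] *= np.exp(eta)
    ebe = [StructuralParams.from_vector(spec.n_compartments, row) for row in P]
    converged = (
        bool(best.success) and np.isfinite(best.fun) and best.fun * n_obs < _PENALTY / 2
    )
    return FitResult(
        spec=spec,
        theta=dict(zip(spec.param_names, map(float, theta))),
        omega=dict(zip(spec.random_effect_params, map(float, omega2))),
        sigma=sigma2,
        ofv=float(ofv),
        converged=converged,
        ebe=ebe,
        eta=eta,
        subject_ids=list(problem.subject_ids),
        ofv_trace=trace,
        n_restarts_used=n_restarts_used,
    )


def empirical_bayes_params(fit_result: FitResult) -> list[StructuralParams]:
    """Per-subject parameters P_i = theta * exp(eta-hat_i)."""
    if not fit_result.converged:
        raise ValueError("empirical Bayes parameters require a converged fit")
    return list(fit_result.ebe)
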