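"""Synthetic-data engine: virtual vancomycin concentration-time profiles.

Individual parameters are drawn from published population PK models with
log-normal between-subject variability truncated at +/-2 SD on the log scale,
covariates fixed at their centering medians (so every covariate multiplier is
exactly 1), and observations perturbed by proportional residual error.
Datasets use a NONMEM-style rectangular layout with columns
ID, TIME, AMT, RATE, DV, EVID, MDV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pk_core import (
    PARAM_NAMES,
    InvalidParameterError,
    Regimen,
    StructuralParams,
    conc_single_matrix,
)

__all__ = [
    "Covariate",
    "PopulationPKModel",
    "SamplingDesign",
    "DATASET_COLUMNS",
    "builtin_models",
    "draw_individual_parameters",
    "simulate_dataset",
    "reduce_design",
    "write_dataset",
    "read_dataset",
]

DATASET_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV"]

#: How a reported %CV of between-subject variability maps to the log-scale SD.
#: "cv" (default): omega = CV, the convention under which NONMEM omega output
#: is quoted as a percentage.  "lognormal_exact": omega^2 = ln(1 + CV^2).
CV_CONVENTIONS = ("cv", "lognormal_exact")

#: Truncation bound for the log-scale random effects, in units of omega.
ETA_TRUNCATION_SD = 2.0


class DesignMismatchError(ValueError):
    """A requested sampling time is absent from the dataset's design."""


@dataclass(frozen=True)
class Covariate:
    """Linear covariate effect P = theta * (1 + slope * (value - center)).

    ``median`` is the population median at which the covariate is fixed
    during simulation; when ``median == center`` the multiplier is 1.
    """

    parameter: str
    slope: float
    name: str
    center: float
    median: float

    def multiplier(self, value: float | None = None) -> float:
        v = self.median if value is None else value
        return 1.0 + self.slope * (v - self.center)


@dataclass(frozen=True)
class PopulationPKModel:
    """A population PK model: typical values, BSV, residual error, covariates."""

    structural: StructuralParams
    bsv: dict[str, float]
    residual_cv: float
    covariates: tuple[Covariate, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        for pname, cv in self.bsv.items():
            if cv < 0:
                raise InvalidParameterError(f"BSV CV for {pname} must be >= 0")
        if self.residual_cv < 0:
            raise InvalidParameterError("residual_cv must be >= 0")

    def omega(self, parameter: str, cv_convention: str = "cv") -> float:
        """Log-scale SD of the random effect for one parameter."""
        cv = self.bsv.get(parameter, 0.0)
        if cv_convention == "cv":
            return cv
        if cv_convention == "lognormal_exact":
            return float(np.sqrt(np.log1p(cv**2)))
        raise ValueError(f"unknown cv_convention {cv_convention!r}")

    def covariate_multipliers(self, values: dict[str, float] | None = None) -> dict[str, float]:
        """Per-parameter covariate multiplier; 1 for all at the medians."""
        mult: dict[str, float] = {}
        for cov in self.covariates:
            v = None if values is None else values.get(cov.name)
            mult[cov.parameter] = mult.get(cov.parameter, 1.0) * cov.multiplier(v)
        return mult


@dataclass(frozen=True)
class SamplingDesign:
    """Ordered blood sampling times (h after the start of infusion)."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InvalidParameterError(
                "sampling times must be non-negative and strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.times)


def builtin_models() -> tuple[PopulationPKModel, PopulationPKModel]:
    """The two published vancomycin population models used for simulation.

    Returns (two_compartment, three_compartment).  Covariates (creatinine
    clearance, body weight, estimated GFR) are carried with their centering
    medians so their multipliers are exactly 1 under the simulation protocol.
    """
    two = PopulationPKModel(
        structural=StructuralParams(2, CL=2.83, V1=24.2, Q1=11.2, V2=32.3),
        bsv={"CL": 0.77, "V1": 0.34},
        residual_cv=0.0819,
        covariates=(
            Covariate("CL", 0.0154, "CLCR", 83.0, 83.0),
            Covariate("V1", 0.00638, "BW", 94.5, 94.5),
            Covariate("V2", 0.0169, "BW", 94.5, 94.5),
        ),
        name="two_compartment",
    )
    three = PopulationPKModel(
        structural=StructuralParams(3, CL=4.01, V1=8.01, Q1=4.95, V2=15.4, Q2=9.09, V3=6.21),
        bsv={"CL": 0.339, "V1": 0.279, "V2": 0.343, "V3": 0.569},
        residual_cv=0.0664,
        covariates=(Covariate("CL", 0.00752, "CE", 56.75, 56.75),),
        name="three_compartment",
    )
    return two, three


def _truncated_normal(rng: np.random.Generator, sd: float, size: int, bound_sd: float) -> np.ndarray:
    """N(0, sd^2) truncated to |x| <= bound_sd * sd, by rejection."""
    if sd == 0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bound = bound_sd * sd
    bad = np.abs(out) > bound
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > bound
    return out


def draw_individual_parameters(
    model: PopulationPKModel,
    n: int,
    rng_seed: int | np.random.Generator,
    cv_convention: str = "cv",
) -> list[StructuralParams]:
    """Draw ``n`` individual parameter sets from the population model.

    P_i = TV * exp(eta) with eta ~ N(0, omega^2) truncated at +/-2 omega;
    parameters without reported BSV stay at their typical values.  Covariates
    are fixed at their medians, so covariate multipliers are 1.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    names = PARAM_NAMES[model.structural.n_compartments]
    tv = model.structural.to_vector()
    mult = model.covariate_multipliers()
    P = np.tile(tv, (n, 1))
    for j, pname in enumerate(names):
        P[:, j] *= mult.get(pname, 1.0)
        omega = model.omega(pname, cv_convention)
        if omega > 0:
            eta = _truncated_normal(rng, omega, n, ETA_TRUNCATION_SD)
            P[:, j] *= np.exp(eta)
    n_cmt = model.structural.n_compartments
    return [StructuralParams.from_vector(n_cmt, row) for row in P]


def simulate_dataset(
    model: PopulationPKModel,
    regimen: Regimen,
    design: SamplingDesign,
    n: int,
    rng_seed: int | np.random.Generator,
    cv_convention: str = "cv",
) -> tuple[pd.DataFrame, list[StructuralParams]]:
    """Simulate an observed single-dose dataset for ``n`` subjects.

    Observations are DV = C * (1 + eps) with eps ~ N(0, residual_cv^2)
    (untruncated); negative observations are floored at 0 and flagged MDV=1.
    Pre-dose t=0 samples are recorded with DV=0 and MDV=1 since a zero
    concentration carries no information under a proportional error model.
    Returns the dataset and the true individual parameters.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    truth = draw_individual_parameters(model, n, rng, cv_convention)
    P = np.array([p.to_vector() for p in truth])
    times = np.asarray(design.times, dtype=float)
    n_cmt = model.structural.n_compartments
    conc = conc_single_matrix(n_cmt, P, regimen.dose, regimen.infusion_duration, times)
    eps = rng.normal(0.0, model.residual_cv, conc.shape)
    dv = conc * (1.0 + eps)

    records = []
    for i in range(n):
        records.append(
            (i + 1, 0.0, regimen.dose, regimen.rate, 0.0, 1, 1)
        )
        for j, t in enumerate(times):
            v = dv[i, j]
            if t == 0.0:
                records.append((i + 1, 0.0, 0.0, 0.0, 0.0, 0, 1))
            elif v < 0.0:
                records.append((i + 1, t, 0.0, 0.0, 0.0, 0, 1))
            else:
                records.append((i + 1, t, 0.0, 0.0, v, 0, 0))
    df = pd.DataFrame.from_records(records, columns=DATASET_COLUMNS)
    return df, truth


def reduce_design(dataset: pd.DataFrame, keep_times: SamplingDesign) -> pd.DataFrame:
    """Restrict observation records to a sparser design (keep dose records).

    Subsets the existing noisy DV values; nothing is re-simulated.  Raises
    DesignMismatchError if a requested time is absent from the dataset.
    """
    obs = dataset[dataset["EVID"] == 0]
    present = set(obs["TIME"].unique())
    missing = [t for t in keep_times.times if t not in present]
    if missing:
        raise DesignMismatchError(f"times {missing} not in the dataset design")
    keep = dataset["EVID"].eq(1) | dataset["TIME"].isin(keep_times.times)
    return dataset.loc[keep].reset_index(drop=True)


def write_dataset(
    dataset: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write the dataset as CSV plus a JSON sidecar with generation metadata."""
    path = Path(path)
    dataset.to_csv(path, index=False)
    if metadata is not None:
        path.with_suffix(".meta.json").write_text(json.dumps(metadata, indent=2))


def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DesignMismatchError(f"dataset is missing columns {missing}")
    return df[DATASET_COLUMNS]
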