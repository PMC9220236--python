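"""Scenario orchestration: the full simulation-estimation-PTA experiment.

Runs the factorial study (truth model x fitted model order x sample size x
replicate): simulate datasets from a published truth model, subset each to
the sampling design paired with the fitted model order, fit by FOCE-I,
summarise bias/precision of CL and Vss, and propagate the n=50 fits to
AUC/MIC probability-of-target-attainment tables.  All randomness derives
from one master seed; per-replicate seeds are spawned deterministically from
(master seed, truth order, sample size, replicate index), so any slice of
the study can be re-run independently and datasets are shared across fitted
model orders within a scenario.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimate import FitResult, ModelSpec, fit
from .exposure_pta import PTAResult, pta_from_fits, write_pta_table
from .metrics import BiasPrecisionEntry, rbias, rrmse, write_bias_table
from .pk_core import Regimen, vss
from .simulate import SamplingDesign, builtin_models, reduce_design, simulate_dataset

__all__ = [
    "ScenarioConfig",
    "FULL_DESIGNS",
    "REDUCED_DESIGNS",
    "SIMULATION_REGIMENS",
    "replicate_fits",
    "run_bias_study",
    "run_pta_study",
    "render_figures",
]

logger = logging.getLogger(__name__)

#: Rich sampling designs (h) used to generate each truth model's profiles.
FULL_DESIGNS = {
    2: (0.0, 2.5, 3.0, 4.0, 6.0, 8.0),
    3: (0.0, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0),
}

#: Design paired with each fitted model order, per truth model.
REDUCED_DESIGNS = {
    2: {1: (0.0, 2.5, 6.0, 8.0), 2: FULL_DESIGNS[2]},
    3: {
        1: (0.0, 1.5, 6.0, 12.0),
        2: (0.0, 1.5, 3.0, 4.0, 8.0, 12.0),
        3: FULL_DESIGNS[3],
    },
}

#: Single-dose regimens used for profile simulation (1 g; 2 h infusion for
#: the two-compartment truth, 1 h for the three-compartment truth).
SIMULATION_REGIMENS = {
    2: Regimen(dose=1000.0, infusion_duration=2.0, interval=12.0, n_doses=1),
    3: Regimen(dose=1000.0, infusion_duration=1.0, interval=12.0, n_doses=1),
}

_TRUTH_ORDER = {"2cmt": 2, "3cmt": 3}


@dataclass
class ScenarioConfig:
    """Configuration for one truth model's factorial study."""

    truth_model: str = "2cmt"
    fit_orders: tuple[int, ...] = (1, 2)
    sample_sizes: tuple[int, ...] = (12, 25, 50, 100)
    n_replicates: int = 200
    doses: tuple[float, ...] = (500.0, 750.0, 1000.0)
    mic: float = 1.0
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.truth_model not in _TRUTH_ORDER:
            raise ValueError("truth_model must be '2cmt' or '3cmt'")
        order = self.truth_order
        if any(o > order or o < 1 for o in self.fit_orders):
            raise ValueError("fit orders must be between 1 and the truth order")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def truth_order(self) -> int:
        return _TRUTH_ORDER[self.truth_model]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("fit_orders", "sample_sizes", "doses"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        for name in ("fit_orders", "sample_sizes", "doses"):
            payload[name] = list(payload[name])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _truth_model(order: int):
    two, three = builtin_models()
    return {2: two, 3: three}[order]


def _dataset_seed(master: int, truth_order: int, n_subjects: int, replicate: int) -> int:
    ss = np.random.SeedSequence([master, truth_order, n_subjects, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def replicate_fits(
    truth_order: int,
    fit_order: int,
    n_subjects: int,
    n_replicates: int,
    master_seed: int,
    progress: bool = False,
) -> list[FitResult]:
    """Simulate ``n_replicates`` datasets and fit each with ``fit_order``.

    Dataset seeds do not depend on the fitted order, so different model
    orders are fitted to the same simulated profiles (subset to the design
    paired with the order).  Returns one FitResult per replicate, including
    any that failed to converge (callers filter and count those).
    """
    model = _truth_model(truth_order)
    regimen = SIMULATION_REGIMENS[truth_order]
    full = SamplingDesign(FULL_DESIGNS[truth_order])
    reduced = SamplingDesign(REDUCED_DESIGNS[truth_order][fit_order])
    spec = ModelSpec(fit_order)
    iterator = range(n_replicates)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(
            iterator,
            desc=f"{truth_order}cmt truth / {fit_order}cmt fit / n={n_subjects}",
        )
    fits = []
    for rep in iterator:
        seed = _dataset_seed(master_seed, truth_order, n_subjects, rep)
        dataset, _ = simulate_dataset(model, regimen, full, n_subjects, seed)
        dataset = reduce_design(dataset, reduced)
        fits.append(fit(dataset, spec, rng_seed=seed))
    return fits


def _vss_estimate(fr: FitResult) -> float:
    return sum(
        fr.theta[name] for name in ("V1", "V2", "V3") if name in fr.theta
    )


def run_bias_study(
    config: ScenarioConfig,
    progress: bool = False,
    fits_cache: dict | None = None,
) -> tuple[list[BiasPrecisionEntry], pd.DataFrame, dict]:
    """RBias/RRMSE of CL and Vss for every (fit order, sample size) cell.

    Returns (entries, raw per-replicate estimates, metadata).  Passing a
    dict as ``fits_cache`` retains the fitted results keyed by
    (fit_order, n_subjects) for reuse (e.g. by the PTA study).
    """
    truth = _truth_model(config.truth_order)
    cl_truth = truth.structural.CL
    vss_truth = vss(truth.structural)
    entries: list[BiasPrecisionEntry] = []
    raw_rows = []
    exclusions: dict[str, int] = {}
    for fit_order in config.fit_orders:
        for n_subjects in config.sample_sizes:
            fits = replicate_fits(
                config.truth_order,
                fit_order,
                n_subjects,
                config.n_replicates,
                config.seed,
                progress=progress,
            )
            if fits_cache is not None:
                fits_cache[(fit_order, n_subjects)] = fits
            ok = [f for f in fits if f.converged]
            exclusions[f"fit{fit_order}_n{n_subjects}"] = len(fits) - len(ok)
            cl_est = [f.theta["CL"] for f in ok]
            vss_est = [_vss_estimate(f) for f in ok]
            for rep, f in enumerate(fits):
                raw_rows.append(
                    {
                        "truth_order": config.truth_order,
                        "fit_order": fit_order,
                        "n_subjects": n_subjects,
                        "replicate": rep,
                        "converged": f.converged,
                        "CL": f.theta["CL"],
                        "Vss": _vss_estimate(f),
                    }
                )
            for pname, est, tv in (
                ("CL", cl_est, cl_truth),
                ("Vss", vss_est, vss_truth),
            ):
                entries.append(
                    BiasPrecisionEntry(
                        truth_order=config.truth_order,
                        fit_order=fit_order,
                        n_subjects=n_subjects,
                        parameter=pname,
                        rbias_pct=rbias(est, tv),
                        rrmse_pct=rrmse(est, tv),
                        n_replicates=len(est),
                    )
                )
    metadata = {
        "seed": config.seed,
        "truth_model": config.truth_model,
        "n_replicates": config.n_replicates,
        "exclusions": exclusions,
        "version": __version__,
    }
    return entries, pd.DataFrame(raw_rows), metadata


def run_pta_study(
    config: ScenarioConfig,
    fits_cache: dict | None = None,
    progress: bool = False,
    pta_n_subjects: int = 50,
) -> dict[int, list[PTAResult]]:
    """Pooled-EBE PTA per fitted order and dose, from n=50 fits only.

    Reuses fits from ``fits_cache`` (as filled by run_bias_study) when
    available; otherwise runs the required fits.  Infusion duration follows
    the truth model's regimen; doses are given every 12 h.
    """
    results: dict[int, list[PTAResult]] = {}
    base = SIMULATION_REGIMENS[config.truth_order]
    for fit_order in config.fit_orders:
        fits = None
        if fits_cache is not None:
            fits = fits_cache.get((fit_order, pta_n_subjects))
        if fits is None:
            fits = replicate_fits(
                config.truth_order,
                fit_order,
                pta_n_subjects,
                config.n_replicates,
                config.seed,
                progress=progress,
            )
            if fits_cache is not None:
                fits_cache[(fit_order, pta_n_subjects)] = fits
        results[fit_order] = [
            pta_from_fits(
                fits,
                Regimen(
                    dose=dose,
                    infusion_duration=base.infusion_duration,
                    interval=base.interval,
                ),
                mic=config.mic,
            )
            for dose in config.doses
        ]
    return results


def render_figures(
    raw_estimates: pd.DataFrame,
    output_dir: str | Path,
    truth_cl: float | None = None,
    truth_vss: float | None = None,
) -> list[Path]:
    """Box plots of CL and Vss estimates by fitted order and sample size.

    Dashed lines mark the simulation truth.  Returns the written file
    paths; an empty input is a warned no-op.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if raw_estimates is None or raw_estimates.empty:
        logger.warning("no estimates to plot")
        return []
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for truth_order, sub in raw_estimates.groupby("truth_order"):
        fig, axes = plt.subplots(
            2, sub["fit_order"].nunique(), figsize=(10, 7), squeeze=False, sharey="row"
        )
        for col, (fit_order, block) in enumerate(sub.groupby("fit_order")):
            for row, (param, truth_line) in enumerate(
                (("CL", truth_cl), ("Vss", truth_vss))
            ):
                ax = axes[row][col]
                groups = [
                    g[param].to_numpy()
                    for _, g in block[block["converged"]].groupby("n_subjects")
                ]
                labels = sorted(block["n_subjects"].unique())
                ax.boxplot(groups, tick_labels=[str(x) for x in labels])
                if truth_line is not None:
                    ax.axhline(truth_line, ls="--", color="grey")
                ax.set_title(f"{fit_order}-compartment fit")
                ax.set_ylabel(f"{param} ({'L/h' if param == 'CL' else 'L'})")
                ax.set_xlabel("subjects per dataset")
        fig.suptitle(f"{truth_order}-compartment truth")
        fig.tight_layout()
        path = output_dir / f"estimates_truth{truth_order}cmt.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def run_all(config: ScenarioConfig, progress: bool = False) -> dict:
    """Bias study + PTA study + figures + metadata for one truth model."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = _truth_model(config.truth_order)
    cache: dict = {}
    entries, raw, metadata = run_bias_study(config, progress=progress, fits_cache=cache)
    bias_table = write_bias_table(entries, out / f"bias_{config.truth_model}.csv")
    raw.to_csv(out / f"estimates_{config.truth_model}.csv", index=False)
    pta_tables = None
    if 50 in config.sample_sizes:
        pta_results = run_pta_study(config, fits_cache=cache, progress=progress)
        pta_tables = write_pta_table(
            pta_results, out / f"pta_{config.truth_model}.csv"
        )
    figures = render_figures(
        raw, out, truth_cl=truth.structural.CL, truth_vss=vss(truth.structural)
    )
    (out / f"metadata_{config.truth_model}.json").write_text(
        json.dumps(metadata, indent=2)
    )
    return {
        "bias": bias_table,
        "pta": pta_tables,
        "figures": figures,
        "metadata": metadata,
    }
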