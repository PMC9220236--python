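"""Synthetic-data engine: published models, truncated BSV, dataset layout."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from sparse_pkpd.pk_core import Regimen, StructuralParams
from sparse_pkpd.simulate import (
    DesignMismatchError,
    PopulationPKModel,
    SamplingDesign,
    builtin_models,
    draw_individual_parameters,
    read_dataset,
    reduce_design,
    simulate_dataset,
    write_dataset,
)

REG = Regimen(dose=1000.0, infusion_duration=2.0, interval=12.0)
DESIGN_6PT = SamplingDesign((0.0, 2.5, 3.0, 4.0, 6.0, 8.0))


class TestBuiltinModels:
    def test_two_compartment_published_values(self):
        two, _ = builtin_models()
        assert two.structural.CL == 2.83
        assert two.structural.V1 == 24.2
        assert two.structural.Q1 == 11.2
        assert two.structural.V2 == 32.3
        assert two.bsv == {"CL": 0.77, "V1": 0.34}
        assert two.residual_cv == 0.0819

    def test_three_compartment_published_values(self):
        _, three = builtin_models()
        s = three.structural
        assert (s.CL, s.V1, s.Q1, s.V2, s.Q2, s.V3) == (4.01, 8.01, 4.95, 15.4, 9.09, 6.21)
        assert three.bsv == {"CL": 0.339, "V1": 0.279, "V2": 0.343, "V3": 0.569}
        assert three.residual_cv == 0.0664

    def test_covariate_multipliers_are_one_at_medians(self):
        for model in builtin_models():
            for mult in model.covariate_multipliers().values():
                assert mult == pytest.approx(1.0, abs=1e-15)


class TestDrawIndividualParameters:
    def test_zero_bsv_returns_typical_values(self):
        model = PopulationPKModel(
            StructuralParams(1, CL=3.0, V1=40.0), bsv={}, residual_cv=0.1
        )
        draws = draw_individual_parameters(model, 5, rng_seed=0)
        assert all(p.CL == 3.0 and p.V1 == 40.0 for p in draws)

    def test_truncation_bound_holds_exactly(self):
        two, _ = builtin_models()
        draws = draw_individual_parameters(two, 10_000, rng_seed=1)
        cl = np.array([p.CL for p in draws])
        lo, hi = 2.83 * np.exp(-2 * 0.77), 2.83 * np.exp(2 * 0.77)
        assert cl.min() >= lo and cl.max() <= hi

    def test_log_mean_is_centered(self):
        """Symmetrically truncated log-normal BSV has zero log-scale mean."""
        two, _ = builtin_models()
        draws = draw_individual_parameters(two, 10_000, rng_seed=2)
        eta = np.log(np.array([p.CL for p in draws]) / 2.83)
        se = eta.std(ddof=1) / np.sqrt(len(eta))
        assert abs(eta.mean()) < 3 * se

    def test_empirical_cv_matches_truncation_adjusted_value(self):
        """Realised CV agrees with the numeric-integration oracle for the
        +/-2 SD truncated log-normal within 5% relative."""
        two, _ = builtin_models()
        draws = draw_individual_parameters(two, 10_000, rng_seed=3)
        cl = np.array([p.CL for p in draws])
        omega = 0.77

        def moment(k):
            norm, _ = quad(
                lambda e: np.exp(-0.5 * e**2 / omega**2), -2 * omega, 2 * omega
            )
            val, _ = quad(
                lambda e: np.exp(k * e) * np.exp(-0.5 * e**2 / omega**2),
                -2 * omega,
                2 * omega,
            )
            return val / norm

        m1, m2 = moment(1), moment(2)
        expected_cv = np.sqrt(m2 - m1**2) / m1
        assert cl.std() / cl.mean() == pytest.approx(expected_cv, rel=0.05)

    def test_lognormal_exact_convention(self):
        two, _ = builtin_models()
        assert two.omega("CL") == 0.77
        assert two.omega("CL", "lognormal_exact") == pytest.approx(
            np.sqrt(np.log1p(0.77**2))
        )


class TestSimulateDataset:
    def test_record_counts(self):
        two, _ = builtin_models()
        ds, truth = simulate_dataset(two, REG, DESIGN_6PT, 12, rng_seed=0)
        assert (ds["EVID"] == 1).sum() == 12
        assert (ds["EVID"] == 0).sum() == 72
        assert len(truth) == 12
        # every subject doses once at time 0
        doses = ds[ds["EVID"] == 1]
        assert doses["TIME"].eq(0.0).all() and doses["ID"].is_unique

    def test_zero_residual_reproduces_model_predictions(self):
        model = PopulationPKModel(
            StructuralParams(1, CL=3.0, V1=40.0), bsv={}, residual_cv=0.0
        )
        ds, _ = simulate_dataset(model, REG, DESIGN_6PT, 3, rng_seed=0)
        from sparse_pkpd.pk_core import concentration_single_dose

        obs = ds[(ds["EVID"] == 0) & (ds["MDV"] == 0)]
        p = StructuralParams(1, CL=3.0, V1=40.0)
        for t, dv in zip(obs["TIME"], obs["DV"]):
            assert dv == pytest.approx(concentration_single_dose(p, REG, t), rel=1e-12)

    def test_time_zero_records_are_flagged_missing(self):
        two, _ = builtin_models()
        ds, _ = simulate_dataset(two, REG, DESIGN_6PT, 4, rng_seed=0)
        t0_obs = ds[(ds["EVID"] == 0) & (ds["TIME"] == 0.0)]
        assert (t0_obs["DV"] == 0.0).all() and (t0_obs["MDV"] == 1).all()

    def test_seeded_reproducibility(self):
        two, _ = builtin_models()
        a, _ = simulate_dataset(two, REG, DESIGN_6PT, 10, rng_seed=99)
        b, _ = simulate_dataset(two, REG, DESIGN_6PT, 10, rng_seed=99)
        pd.testing.assert_frame_equal(a, b)


class TestReduceDesign:
    def test_identity_when_keeping_all_times(self):
        two, _ = builtin_models()
        ds, _ = simulate_dataset(two, REG, DESIGN_6PT, 5, rng_seed=0)
        pd.testing.assert_frame_equal(reduce_design(ds, DESIGN_6PT), ds)

    def test_subset_keeps_same_noisy_values(self):
        """Reduction subsets existing observations; nothing is re-simulated."""
        two, _ = builtin_models()
        ds, _ = simulate_dataset(two, REG, DESIGN_6PT, 5, rng_seed=0)
        red = reduce_design(ds, SamplingDesign((0.0, 2.5, 6.0, 8.0)))
        obs = red[red["EVID"] == 0]
        assert len(obs) == 5 * 4
        merged = obs.merge(ds[ds["EVID"] == 0], on=["ID", "TIME"], suffixes=("_r", "_f"))
        assert (merged["DV_r"] == merged["DV_f"]).all()

    def test_nine_point_to_six_point(self):
        _, three = builtin_models()
        reg = Regimen(dose=1000.0, infusion_duration=1.0, interval=12.0)
        full = SamplingDesign((0.0, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0))
        ds, _ = simulate_dataset(three, reg, full, 4, rng_seed=0)
        red = reduce_design(ds, SamplingDesign((0.0, 1.5, 3.0, 4.0, 8.0, 12.0)))
        assert (red["EVID"] == 0).sum() == 4 * 6

    def test_missing_time_raises(self):
        two, _ = builtin_models()
        ds, _ = simulate_dataset(two, REG, DESIGN_6PT, 3, rng_seed=0)
        with pytest.raises(DesignMismatchError):
            reduce_design(ds, SamplingDesign((0.0, 5.0)))


def test_csv_roundtrip(tmp_path):
    two, _ = builtin_models()
    ds, _ = simulate_dataset(two, REG, DESIGN_6PT, 4, rng_seed=7)
    path = tmp_path / "data.csv"
    write_dataset(ds, path, metadata={"seed": 7, "design": list(DESIGN_6PT.times)})
    back = read_dataset(path)
    pd.testing.assert_frame_equal(back, ds, check_dtype=False)
    assert (tmp_path / "data.meta.json").exists()
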