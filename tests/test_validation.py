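"""Precision, trueness, LOQ, Horwitz and the assembled validation report."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import residuval as rv
from residuval.calibration import CalibrationMode
from residuval.core_io import ResiduvalError, Thresholds
from residuval.validation import (
    DesignIncompletenessError,
    InsufficientReplicatesError,
    NoLOQError,
    UndefinedRSDError,
    compute_flags,
    determine_loq,
    precision_table,
)

from conftest import make_noiseless


class TestRSD:
    def test_constant_values_have_zero_rsd(self):
        assert rv.rsd([10, 10, 10, 10]) == 0.0

    def test_textbook_example(self):
        assert rv.rsd([9, 10, 11]) == pytest.approx(10.0)  # SD = 1, mean = 10

    @given(
        st.lists(st.floats(1, 1e4), min_size=2, max_size=12),
    )
    @settings(derandomize=True, max_examples=100)
    def test_matches_two_pass_oracle(self, values):
        mean = sum(values) / len(values)
        sd = (sum((v - mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5
        assert rv.rsd(values) == pytest.approx(100 * sd / mean, rel=1e-12, abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            rv.rsd([10.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedRSDError):
            rv.rsd([-1.0, 1.0])


class TestRecoveries:
    def test_relative_recovery_examples(self):
        assert rv.relative_recovery(10, 10) == 100.0
        assert rv.relative_recovery(5.02, 10) == pytest.approx(50.2)

    def test_relative_recovery_requires_positive_spike(self):
        with pytest.raises(ResiduvalError):
            rv.relative_recovery(5, 0)

    def test_absolute_recovery_reference_cases(self):
        assert rv.absolute_recovery(500, 1000, 0.5) == pytest.approx(100.0)
        assert rv.absolute_recovery(250, 1000, 0.5) == pytest.approx(50.0)

    def test_absolute_recovery_guards_denominators(self):
        with pytest.raises(ResiduvalError):
            rv.absolute_recovery(500, 0, 0.5)
        with pytest.raises(ResiduvalError):
            rv.absolute_recovery(500, 1000, 0)

    def test_low_extraction_recovery_measured_from_areas(
        self, small_registry, design
    ):
        """An IL-IS extracted at 43% shows a 43% absolute recovery against
        the syringe standard, noise-free."""
        truth = make_noiseless(rv.default_truth(small_registry, seed=8))
        recovery = dict(truth.extraction_recovery)
        recovery["alachlor-D13"] = 0.43
        truth = dataclasses.replace(truth, extraction_recovery=recovery)
        inj, smp = rv.simulate_dataset(small_registry, design, truth)
        areas = {
            (r.sample_id, r.compound): r.area
            for r in inj
            if r.transition_role is rv.TransitionRole.QUANTIFIER
        }
        cal = next(
            m for m in smp if m.role is rv.SampleRole.MM_CAL and m.matrix == "SR"
        )
        fort = next(
            m for m in smp if m.role is rv.SampleRole.FORTIFIED and m.matrix == "SR"
        )
        cal_ratio = areas[(cal.sample_id, "alachlor-D13")] / areas[(cal.sample_id, "TPP")]
        value = rv.absolute_recovery(
            areas[(fort.sample_id, "alachlor-D13")],
            areas[(fort.sample_id, "TPP")],
            cal_ratio,
        )
        assert value == pytest.approx(43.0, abs=1e-9)


class TestHorwitz:
    def test_reference_points(self):
        assert rv.horwitz(1e-8).rsd_bl == pytest.approx(32.0)  # 10 ng/g
        assert rv.horwitz(1e-2).rsd_bl == pytest.approx(4.0)

    @given(st.floats(1e-10, 1e-1))
    @settings(derandomize=True, max_examples=50)
    def test_within_lab_is_two_thirds_of_between_lab(self, c):
        b = rv.horwitz(c)
        assert b.rsd_wl / b.rsd_bl == pytest.approx(2 / 3)

    def test_halves_when_concentration_grows_hundredfold(self):
        assert rv.horwitz(1e-6).rsd_bl == pytest.approx(rv.horwitz(1e-8).rsd_bl / 2)

    def test_mass_fraction_conversion(self):
        assert rv.mass_fraction(10.0) == pytest.approx(1e-8)

    def test_domain_error(self):
        with pytest.raises(ResiduvalError):
            rv.horwitz(0.0)


class TestDetermineLOQ:
    def test_lowest_level_meeting_both_criteria(self):
        series = [(0.1, 3, 1), (0.5, 8, 2), (1, 12, 5), (5, 40, 20)]
        assert determine_loq(series) == 1.0

    def test_all_levels_qualify_gives_lowest(self):
        series = [(0.1, 20, 5), (0.5, 80, 20), (1, 120, 50)]
        assert determine_loq(series) == pytest.approx(0.1)

    def test_boundary_is_strict(self):
        assert determine_loq([(1, 10.0, 5), (5, 10.1, 5)]) == 5.0
        with pytest.raises(NoLOQError):
            determine_loq([(1, 10.0, 5), (5, 11.0, 3.0)])

    def test_units_policy_converts_to_soil_basis(self):
        policy = rv.ConcentrationUnitsPolicy(2.0)
        assert determine_loq([(1, 12, 4)], policy) == 2.0


class TestPrecisionTable:
    def frame(self, concs):
        rows = []
        for (day, rep), c in concs.items():
            rows.append(
                {"compound": "x", "level": 10.0, "day": day, "replicate": rep, "conc": c}
            )
        return pd.DataFrame(rows)

    def test_identical_concentrations_give_zero_rsds(self):
        concs = {(d, r): 10.0 for d in (1, 2, 3) for r in (1, 2, 3, 4)}
        out = precision_table(self.frame(concs))
        assert out.loc[0, "rsd_r"] == 0.0
        assert out.loc[0, "rsd_R"] == 0.0

    def test_repeatability_uses_designated_day(self):
        concs = {(1, r): 10.0 for r in (1, 2)} | {(2, r): v for r, v in ((1, 9.0), (2, 11.0))}
        out = precision_table(self.frame(concs), repeatability_day=2)
        assert out.loc[0, "rsd_r"] == pytest.approx(rv.rsd([9.0, 11.0]))

    def test_missing_cell_reported_by_name(self):
        concs = {(1, 1): 10.0, (1, 2): 10.0, (2, 1): 10.0}
        with pytest.raises(DesignIncompletenessError, match="day 2"):
            precision_table(self.frame(concs))

    def test_day_effects_inflate_reproducibility(self, registry, design):
        """With between-day variation on, RSDR exceeds RSDr in expectation;
        with it off, the two agree within Monte-Carlo error."""
        base = make_noiseless(rv.default_truth(registry, seed=21))
        quiet = dataclasses.replace(base, injection_cv=0.05)
        noisy = dataclasses.replace(base, injection_cv=0.05, day_effect_sd=0.15)

        def mean_rsds(truth, seed):
            inj, smp = rv.simulate_dataset(registry, design, truth, seed=seed)
            records = rv.build_validation_report(inj, smp, registry)
            r = np.mean([v for rec in records for v in rec.rsd_r.values()])
            R = np.mean([v for rec in records for v in rec.rsd_R.values()])
            return r, R

        r_q, R_q = mean_rsds(quiet, 101)
        assert R_q == pytest.approx(r_q, rel=0.35)

        r_n, R_n = mean_rsds(noisy, 102)
        assert R_n > r_n


class TestReport:
    def test_noise_free_relative_recovery_is_recovery_ratio(
        self, noiseless_data, registry, noiseless_truth
    ):
        """Noise-free relative recovery equals 100 * r_analyte / r_ilis,
        hence exactly 100% for structure-identical pairs."""
        inj, smp = noiseless_data
        records = rv.build_validation_report(inj, smp, registry)
        ilis = {
            r.ilis_group: r for r in registry
            if r.category is rv.Category.INTERNAL_STANDARD
        }
        t = noiseless_truth
        for rec in records:
            reg = next(r for r in registry if r.name == rec.compound)
            expected = 100.0 * (
                t.extraction_recovery[rec.compound]
                / t.extraction_recovery[ilis[reg.ilis_group].name]
            )
            for value in rec.relative_recovery.values():
                assert value == pytest.approx(expected, abs=1e-8)
            if reg.si_ilis:
                assert rec.mean_relative_recovery == pytest.approx(100.0, abs=1e-8)

    def test_summary_rows_equal_independent_recomputation(self, noisy_data, registry):
        inj, smp = noisy_data
        records = rv.build_validation_report(inj, smp, registry)
        summary = rv.summarize_report(records)
        loqs = [r.loq for r in records]
        assert summary.loc["mean", "loq"] == pytest.approx(np.mean(loqs))
        assert summary.loc["min", "loq"] == min(loqs)
        assert summary.loc["max", "loq"] == max(loqs)
        rsdr10 = [r.rsd_r[10.0] for r in records]
        assert summary.loc["mean", "rsdr_10"] == pytest.approx(np.mean(rsdr10))

    def test_flags_are_monotone_in_thresholds(self, table2):
        """Tightening any threshold never turns a fail into a pass."""
        loose = Thresholds()
        tight = dataclasses.replace(
            loose,
            rsdr_max_pct=10.0, rsdR_max_pct=12.0,
            recovery_min_pct=85.0, recovery_max_pct=110.0,
            recovery_ext_min_pct=75.0, recovery_ext_max_pct=125.0,
            r_squared_min=0.997, loq_max_ng_g=5.0,
        )
        for record in table2:
            assert compute_flags(record, tight) <= compute_flags(record, loose)

    def test_table2_fixture_flags(self, table2):
        """Bifenthrin is the only analyte failing the 70-120% trueness
        criterion on its level means in the printed table."""
        failing = [
            r.compound for r in table2
            if not all(70 <= v <= 120 for v in [r.mean_relative_recovery])
        ]
        assert failing == ["Bifenthrin"]
        flags = compute_flags(next(r for r in table2 if r.compound == "Bifenthrin"))
        assert "recovery_pass" not in flags
        assert "linearity_pass" in flags
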