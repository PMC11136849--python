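"""Generator contracts: determinism, the noise model, ground-truth recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import residuval as rv
from residuval.calibration import CalibrationMode, fit_all_curves
from residuval.core_io import RecordValidationError
from residuval.matrix_effects import matrix_effects_from_curves
from residuval.synthetic import ConfigurationError

from conftest import make_noiseless


def test_same_seed_reproduces_identical_datasets(small_registry):
    design = rv.DesignSpec()
    truth = rv.default_truth(small_registry, seed=3)
    a = rv.simulate_dataset(small_registry, design, truth)
    b = rv.simulate_dataset(small_registry, design, truth)
    assert a == b


def test_different_seeds_give_different_noise(small_registry):
    design = rv.DesignSpec()
    truth = rv.default_truth(small_registry, seed=3)
    a, _ = rv.simulate_dataset(small_registry, design, truth, seed=1)
    b, _ = rv.simulate_dataset(small_registry, design, truth, seed=2)
    assert a != b


def test_noise_free_areas_equal_forward_model(small_registry, design):
    """With all noise off, f = 1 and recovery = 1, area = rf * conc exactly."""
    truth = make_noiseless(rv.default_truth(small_registry, seed=5))
    truth = dataclasses.replace(
        truth,
        matrix_factor={k: 1.0 for k in truth.matrix_factor},
        extraction_recovery={k: 1.0 for k in truth.extraction_recovery},
    )
    inj, smp = rv.simulate_dataset(small_registry, design, truth)
    meta = {m.sample_id: m for m in smp}
    for r in inj:
        m = meta[r.sample_id]
        if r.transition_role is rv.TransitionRole.QUANTIFIER and m.role in (
            rv.SampleRole.SOLVENT_CAL, rv.SampleRole.MM_CAL,
        ) and r.compound in ("alachlor", "acetochlor"):
            assert r.area == pytest.approx(
                truth.response_factor[r.compound] * m.nominal_conc, rel=1e-12
            )


def test_uniform_matrix_factor_forces_me_of_50_percent(small_registry, design):
    truth = make_noiseless(rv.default_truth(small_registry, seed=5))
    truth = dataclasses.replace(
        truth, matrix_factor={k: 1.5 for k in truth.matrix_factor}
    )
    inj, smp = rv.simulate_dataset(small_registry, design, truth)
    curves = fit_all_curves(inj, smp, small_registry, CalibrationMode.EXTERNAL)
    for me in matrix_effects_from_curves(curves):
        assert me.me_pct == pytest.approx(50.0, abs=1e-9)


def test_injection_cv_reproduces_lognormal_area_cv(small_registry):
    """1000 replicate injections at one level: empirical CV within 0.045-0.055."""
    design = rv.DesignSpec(
        calibration_levels=(5.0, 10.0, 25.0),
        matrices=("solvent", "SR"),
        fortification_levels=(25.0,),
        replicates_per_level=1000,
        days=1,
    )
    truth = make_noiseless(rv.default_truth(small_registry, seed=19))
    truth = dataclasses.replace(truth, injection_cv=0.05)
    inj, smp = rv.simulate_dataset(small_registry, design, truth, seed=19)
    fortified = {m.sample_id for m in smp if m.role is rv.SampleRole.FORTIFIED}
    areas = np.array(
        [
            r.area
            for r in inj
            if r.sample_id in fortified
            and r.compound == "alachlor"
            and r.transition_role is rv.TransitionRole.QUANTIFIER
        ]
    )
    assert len(areas) == 1000
    cv = areas.std(ddof=1) / areas.mean()
    assert 0.045 < cv < 0.055


def test_mean_area_linear_in_level_noise_free(noiseless_data, registry):
    """Regression of area on level is exact (R^2 > 0.999) without noise."""
    inj, smp = noiseless_data
    meta = {m.sample_id: m for m in smp}
    levels, areas = [], []
    for r in inj:
        m = meta[r.sample_id]
        if (
            m.role is rv.SampleRole.MM_CAL
            and m.matrix == "SR"
            and r.compound == "Atrazine"
            and r.transition_role is rv.TransitionRole.QUANTIFIER
        ):
            levels.append(m.nominal_conc)
            areas.append(r.area)
    fit = stats.linregress(levels, areas)
    assert fit.rvalue**2 > 0.999


def test_si_pairs_share_matrix_factor_and_recovery(registry, noisy_truth):
    ilis = {r.ilis_group: r for r in registry if r.category is rv.Category.INTERNAL_STANDARD}
    for rec in registry:
        if rec.is_analyte and rec.si_ilis:
            partner = ilis[rec.ilis_group]
            assert noisy_truth.extraction_recovery[rec.name] == (
                noisy_truth.extraction_recovery[partner.name]
            )
            for m in ("SR", "RFNo", "XFN"):
                assert noisy_truth.get_matrix_factor(rec.name, m) == (
                    noisy_truth.get_matrix_factor(partner.name, m)
                )


class TestMonitoring:
    def test_zero_prevalence_yields_no_analyte_signal(self, small_registry):
        truth = make_noiseless(rv.default_truth(small_registry, seed=2))
        inj, smp = rv.simulate_monitoring(small_registry, truth, 20, 0.0, seed=2)
        assert len(smp) == 20
        analyte_areas = [
            r.area for r in inj if r.compound in ("alachlor", "acetochlor")
        ]
        assert all(a == 0 for a in analyte_areas)

    def test_full_prevalence_detected_everywhere(self, small_registry):
        truth = make_noiseless(rv.default_truth(small_registry, seed=2))
        inj, smp = rv.simulate_monitoring(
            small_registry, truth, 50, 1.0, (np.log(100.0), 0.1), seed=2
        )
        quant = [
            r for r in inj
            if r.compound == "alachlor" and r.transition_role is rv.TransitionRole.QUANTIFIER
        ]
        assert len(quant) == 50
        assert all(r.area > 0 for r in quant)

    def test_observed_prevalence_within_binomial_interval(self, small_registry):
        """prevalence 0.7 at n=500: count within the binomial 99% interval."""
        truth = make_noiseless(rv.default_truth(small_registry, seed=4))
        inj, smp = rv.simulate_monitoring(
            small_registry, truth, 500, 0.7, (np.log(100.0), 0.2), seed=4
        )
        hits = sum(
            1 for r in inj
            if r.compound == "alachlor"
            and r.transition_role is rv.TransitionRole.QUANTIFIER
            and r.area > 0
        )
        lo, hi = stats.binom.interval(0.99, 500, 0.7)
        assert lo <= hits <= hi

    def test_invalid_inputs_rejected(self, small_registry):
        truth = rv.default_truth(small_registry, seed=2)
        with pytest.raises(RecordValidationError):
            rv.simulate_monitoring(small_registry, truth, 0, 0.5)
        with pytest.raises(RecordValidationError):
            rv.simulate_monitoring(small_registry, truth, 5, 1.5)


def test_missing_truth_entry_is_configuration_error(small_registry, design):
    truth = rv.default_truth(small_registry[:2], seed=1)
    with pytest.raises(ConfigurationError):
        rv.simulate_dataset(small_registry, design, truth)


def test_negative_cv_rejected(small_registry):
    with pytest.raises(RecordValidationError):
        dataclasses.replace(rv.default_truth(small_registry, seed=1), injection_cv=-0.1)


def test_blank_contamination_scenario(small_registry, design):
    """An incurred residue shows up in unspiked blanks of the flagged compound."""
    truth = make_noiseless(rv.default_truth(small_registry, seed=6))
    truth = rv.with_blank_contamination(truth, {"alachlor": 8.0})
    inj, smp = rv.simulate_dataset(small_registry, design, truth)
    blanks = {m.sample_id for m in smp if m.role is rv.SampleRole.BLANK}
    areas = {
        r.compound: r.area
        for r in inj
        if r.sample_id in blanks and r.transition_role is rv.TransitionRole.QUANTIFIER
    }
    assert areas["alachlor"] > 0
    assert areas["acetochlor"] == 0
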