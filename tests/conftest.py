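"""Shared fixtures: the default registry and synthetic datasets.

Session-scoped so the simulated datasets are generated once per run.
"""

from __future__ import annotations

import dataclasses

import pytest

import residuval as rv


def make_noiseless(truth: rv.GroundTruthLedger) -> rv.GroundTruthLedger:
    """Strip every stochastic term from a ground-truth ledger."""
    return dataclasses.replace(
        truth, injection_cv=0.0, day_effect_sd=0.0, ion_ratio_cv=0.0, rt_jitter_sd=0.0
    )


@pytest.fixture(scope="session")
def registry():
    return rv.load_registry()


@pytest.fixture(scope="session")
def design():
    return rv.DesignSpec()


@pytest.fixture(scope="session")
def si_flags(registry):
    return {r.name: r.si_ilis for r in registry}


@pytest.fixture(scope="session")
def noiseless_truth(registry):
    return make_noiseless(rv.default_truth(registry, seed=7))


@pytest.fixture(scope="session")
def noiseless_data(registry, design, noiseless_truth):
    return rv.simulate_dataset(registry, design, noiseless_truth)


@pytest.fixture(scope="session")
def noisy_truth(registry):
    return rv.default_truth(registry, seed=11)


@pytest.fixture(scope="session")
def noisy_data(registry, design, noisy_truth):
    return rv.simulate_dataset(registry, design, noisy_truth)


@pytest.fixture(scope="session")
def table2():
    return rv.load_table2_fixture()


@pytest.fixture(scope="session")
def small_registry():
    """Two analytes (one si, one nsi) sharing one IL-IS, plus the syringe standard."""
    return [
        rv.CompoundRecord("alachlor", rv.Category.HERBICIDE, 1, True, 8.0),
        rv.CompoundRecord("acetochlor", rv.Category.HERBICIDE, 1, False, 8.4),
        rv.CompoundRecord("alachlor-D13", rv.Category.INTERNAL_STANDARD, 1, False, 7.99),
        rv.CompoundRecord("TPP", rv.Category.SYRINGE_STANDARD, 0, False, 12.7),
    ]
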