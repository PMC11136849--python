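"""Synthetic peak-area generator with a known ground truth.

Emulates the measurement model behind a matrix-matched, internal-standard
GC-MS/MS quantification study: every quantifier peak area is

    area = response_factor * conc_extract * matrix_factor
           * extraction_recovery (processed samples only)
           * day_multiplier * exp(eps),   eps ~ Normal(0, ln(1 + cv^2))

where ``conc_extract`` is the compound's concentration in the injected
extract (ng/mL), ``matrix_factor`` the multiplicative signal enhancement or
suppression of the sample's matrix (1 in pure solvent), and the lognormal
``exp(eps)`` term the injection-to-injection noise (so peak-area CVs, not
SDs, are constant across levels). Calibration standards are spiked into the
final extract and therefore bypass the extraction-recovery factor; fortified
and monitoring samples pass through it. Qualifier areas are the quantifier
times a per-compound ion ratio with independent multiplicative noise, and
S/N values are emitted as area over a constant per-compound baseline-noise
area (no chromatogram is simulated).

Day-to-day effects are per-(compound, day) lognormal multipliers drawn
independently for every compound. An earlier design used a single shared
multiplier per day, but a factor common to an analyte and its internal
standard cancels exactly in the area ratio, leaving internal-standard
reproducibility equal to repeatability; independent per-compound day effects
survive the normalization and give the expected RSDR > RSDr ordering.

Structure-identical IL-IS (and all analytes that share one) share their
matrix factors and extraction recovery exactly — this is what makes the
internal-standard matrix effect vanish for those compounds and is the basis
of the parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    Category,
    CompoundRecord,
    ConcentrationUnitsPolicy,
    InjectionRecord,
    RecordValidationError,
    ResiduvalError,
    SampleMeta,
    SampleRole,
    TransitionRole,
)

__all__ = [
    "DesignSpec",
    "GroundTruthLedger",
    "default_truth",
    "simulate_dataset",
    "simulate_monitoring",
    "with_blank_contamination",
]


class ConfigurationError(ResiduvalError):
    """The ground truth does not cover the registry."""


# Median matrix enhancement per soil type. The soils of the study all showed
# net ion enhancement, strongest in SR and DC and weakest in the organically
# managed RFNo; sand is nearly clean.
_MATRIX_MEDIAN_F = {
    "solvent": 1.0,
    "SR": 2.2,
    "RFNo": 1.3,
    "RFNc": 1.8,
    "XFN": 2.0,
    "DC": 2.2,
    "sand": 1.05,
    "other": 1.5,
}
_MATRIX_SIGMA_F = 0.45  # lognormal spread of per-compound matrix factors


@dataclass(frozen=True)
class DesignSpec:
    """The validation study design.

    Six calibration levels (the 0 ng/mL level never enters fitting),
    fortification at 10/25/50 ng/g in quadruplicate on each of three days,
    matrix-matched calibration in five soils plus the solvent, IL-IS and
    syringe standard both at a nominal 10 ng/g.
    """

    calibration_levels: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 75.0, 100.0)
    cal_replicates: int = 1
    fortification_levels: tuple[float, ...] = (10.0, 25.0, 50.0)
    replicates_per_level: int = 4
    days: int = 3
    matrices: tuple[str, ...] = ("solvent", "SR", "RFNo", "RFNc", "XFN", "DC")
    validation_matrix: str = "SR"
    blanks_per_day: int = 1
    ilis_nominal: float = 10.0
    tpp_nominal: float = 10.0

    def __post_init__(self) -> None:
        if any(lv <= 0 for lv in self.calibration_levels):
            raise RecordValidationError("calibration levels must be > 0 (0 is excluded)")
        if self.replicates_per_level < 2:
            raise RecordValidationError("need >= 2 replicates for precision statistics")


@dataclass
class GroundTruthLedger:
    """True generator parameters, kept for parameter-recovery tests.

    ``response_factor`` maps compound -> detector response per (ng/mL);
    ``matrix_factor`` maps (compound, matrix) -> multiplicative enhancement
    (identically 1 in solvent); ``extraction_recovery`` maps compound ->
    extracted fraction; ``ion_ratio`` maps compound -> qualifier/quantifier
    area ratio; ``blank_level`` maps compound -> incurred soil concentration
    (ng/g) present even in unspiked samples.
    """

    response_factor: dict[str, float]
    matrix_factor: dict[tuple[str, str], float]
    extraction_recovery: dict[str, float]
    ion_ratio: dict[str, float]
    blank_level: dict[str, float]
    day_effect_sd: float = 0.08
    injection_cv: float = 0.05
    ion_ratio_cv: float = 0.05
    rt_jitter_sd: float = 0.02
    noise_area_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.injection_cv < 0 or self.day_effect_sd < 0 or self.ion_ratio_cv < 0:
            raise RecordValidationError("noise parameters must be >= 0")

    def get_matrix_factor(self, compound: str, matrix: str) -> float:
        if matrix == "solvent":
            return 1.0
        try:
            return self.matrix_factor[(compound, matrix)]
        except KeyError:
            raise ConfigurationError(
                f"no matrix factor for ({compound!r}, {matrix!r})"
            ) from None

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["matrix_factor"] = {
            f"{c}|{m}": v for (c, m), v in self.matrix_factor.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def default_truth(
    registry: Sequence[CompoundRecord],
    matrices: Iterable[str] = ("SR", "RFNo", "RFNc", "XFN", "DC", "sand"),
    seed: int = 0,
    *,
    injection_cv: float = 0.05,
    day_effect_sd: float = 0.08,
    ion_ratio: float = 0.5,
) -> GroundTruthLedger:
    """Draw a ground-truth ledger with realistic magnitudes.

    Response factors are lognormal around 1000 area units per (ng/mL),
    extraction recoveries normal around 0.9 (clipped to [0.4, 1]), and matrix
    factors lognormal with soil-specific medians between 1.3 and 2.2 —
    predominantly enhancement, as co-extracted soil organic matter protects
    analytes in the hot GC inlet. Compounds sharing a structure-identical
    IL-IS receive identical matrix factors and recoveries.
    """
    rng = np.random.default_rng(seed)
    matrices = [m for m in matrices if m != "solvent"]
    response_factor: dict[str, float] = {}
    extraction_recovery: dict[str, float] = {}
    matrix_factor: dict[tuple[str, str], float] = {}
    ion_ratios: dict[str, float] = {}

    # Compounds that must share matrix behaviour: a structure-identical IL-IS
    # and every analyte flagged si in its group are physically (near-)identical
    # molecules, so they get one common draw.
    si_groups: dict[int, list[str]] = {}
    for rec in registry:
        if rec.si_ilis or rec.category is Category.INTERNAL_STANDARD:
            si_groups.setdefault(rec.ilis_group, []).append(rec.name)

    shared_mf: dict[int, dict[str, float]] = {}
    shared_rec: dict[int, float] = {}
    for group in sorted(si_groups):
        shared_mf[group] = {
            m: float(np.exp(np.log(_MATRIX_MEDIAN_F[m]) + rng.normal(0, _MATRIX_SIGMA_F)))
            for m in matrices
        }
        shared_rec[group] = float(np.clip(rng.normal(0.9, 0.08), 0.4, 1.0))

    for rec in registry:
        response_factor[rec.name] = float(np.exp(rng.normal(np.log(1000.0), 0.5)))
        ion_ratios[rec.name] = ion_ratio
        shared = rec.si_ilis or rec.category is Category.INTERNAL_STANDARD
        if rec.category is Category.SYRINGE_STANDARD:
            # spiked just before injection: nothing to extract
            extraction_recovery[rec.name] = 1.0
        elif shared and rec.ilis_group in shared_rec:
            extraction_recovery[rec.name] = shared_rec[rec.ilis_group]
        else:
            extraction_recovery[rec.name] = float(np.clip(rng.normal(0.9, 0.08), 0.4, 1.0))
        for m in matrices:
            if shared and rec.ilis_group in shared_mf:
                matrix_factor[(rec.name, m)] = shared_mf[rec.ilis_group][m]
            else:
                matrix_factor[(rec.name, m)] = float(
                    np.exp(np.log(_MATRIX_MEDIAN_F[m]) + rng.normal(0, _MATRIX_SIGMA_F))
                )

    return GroundTruthLedger(
        response_factor=response_factor,
        matrix_factor=matrix_factor,
        extraction_recovery=extraction_recovery,
        ion_ratio=ion_ratios,
        blank_level={rec.name: 0.0 for rec in registry},
        day_effect_sd=day_effect_sd,
        injection_cv=injection_cv,
        seed=seed,
    )


def with_blank_contamination(
    truth: GroundTruthLedger, levels: Mapping[str, float]
) -> GroundTruthLedger:
    """A copy of ``truth`` with incurred blank residues for some compounds.

    This reproduces the situation of a transformation product appearing in
    unspiked control soil (the metribuzin DADK scenario): the listed soil
    concentrations (ng/g) are present in every processed sample of the
    affected compounds, blanks included.
    """
    blank = dict(truth.blank_level)
    for name, level in levels.items():
        if name not in blank:
            raise ConfigurationError(f"{name!r} not covered by the ledger")
        if level < 0:
            raise RecordValidationError("blank level must be >= 0")
        blank[name] = float(level)
    return dataclasses.replace(truth, blank_level=blank)


def _sigma_from_cv(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


class _AreaModel:
    """Draws peak areas for one dataset; owns the RNG and the day effects."""

    def __init__(
        self,
        registry: Sequence[CompoundRecord],
        truth: GroundTruthLedger,
        rng: np.random.Generator,
        n_days: int,
        units: ConcentrationUnitsPolicy,
    ) -> None:
        self.registry = list(registry)
        self.truth = truth
        self.rng = rng
        self.units = units
        self.sigma_inj = _sigma_from_cv(truth.injection_cv)
        self.sigma_ratio = _sigma_from_cv(truth.ion_ratio_cv)
        missing = [r.name for r in registry if r.name not in truth.response_factor]
        if missing:
            raise ConfigurationError(f"no ground truth for compounds: {missing}")
        # independent per-(compound, day) lognormal day effects
        self.day_mult = {
            (rec.name, day): float(np.exp(rng.normal(0.0, truth.day_effect_sd)))
            if truth.day_effect_sd > 0
            else 1.0
            for rec in registry
            for day in range(1, n_days + 1)
        }

    def extract_conc(self, rec: CompoundRecord, meta: SampleMeta, design: DesignSpec) -> float:
        """Concentration of ``rec`` in the injected extract, ng/mL."""
        t = self.truth
        processed = meta.role in (SampleRole.BLANK, SampleRole.FORTIFIED, SampleRole.MONITORING)
        if rec.category is Category.SYRINGE_STANDARD:
            return self.units.to_ng_per_ml(design.tpp_nominal)
        if rec.category is Category.INTERNAL_STANDARD:
            if processed:
                return self.units.to_ng_per_ml(
                    design.ilis_nominal * t.extraction_recovery[rec.name]
                )
            return design.ilis_nominal  # spiked into the calibration solution
        if processed:
            soil_conc = meta.nominal_conc + t.blank_level.get(rec.name, 0.0)
            return self.units.to_ng_per_ml(soil_conc * t.extraction_recovery[rec.name])
        return meta.nominal_conc  # calibration standard in the extract

    def records_for(
        self, rec: CompoundRecord, meta: SampleMeta, design: DesignSpec
    ) -> list[InjectionRecord]:
        t = self.truth
        conc = self.extract_conc(rec, meta, design)
        f = t.get_matrix_factor(rec.name, meta.matrix)
        day = self.day_mult[(rec.name, meta.day)]
        eps = (
            float(np.exp(self.rng.normal(0.0, self.sigma_inj)))
            if self.sigma_inj > 0
            else 1.0
        )
        quant_area = t.response_factor[rec.name] * conc * f * day * eps
        ratio_noise = (
            float(np.exp(self.rng.normal(0.0, self.sigma_ratio)))
            if self.sigma_ratio > 0
            else 1.0
        )
        qual_area = quant_area * t.ion_ratio[rec.name] * ratio_noise
        noise_area = t.response_factor[rec.name] * t.noise_area_fraction
        rt = rec.expected_rt + (
            float(self.rng.normal(0.0, t.rt_jitter_sd)) if t.rt_jitter_sd > 0 else 0.0
        )
        rt = max(rt, 0.01)
        out = [
            InjectionRecord(meta.sample_id, rec.name, TransitionRole.QUANTIFIER,
                            quant_area, rt, quant_area / noise_area),
            InjectionRecord(meta.sample_id, rec.name, TransitionRole.QUALIFIER,
                            qual_area, rt, qual_area / noise_area),
        ]
        return out


def simulate_dataset(
    registry: Sequence[CompoundRecord],
    design: DesignSpec,
    truth: GroundTruthLedger,
    *,
    seed: int | None = None,
    units: ConcentrationUnitsPolicy | None = None,
) -> tuple[list[InjectionRecord], list[SampleMeta]]:
    """Generate a full validation dataset.

    Produces solvent and matrix-matched calibration series for every matrix
    in the design, fortified quadruplicates at every fortification level on
    every day (in the validation matrix), and one unspiked blank per day.
    The same seed yields byte-identical output.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    units = units or ConcentrationUnitsPolicy()
    model = _AreaModel(registry, truth, rng, design.days, units)

    metas: list[SampleMeta] = []
    for matrix in design.matrices:
        role = SampleRole.SOLVENT_CAL if matrix == "solvent" else SampleRole.MM_CAL
        for level in design.calibration_levels:
            for rep in range(1, design.cal_replicates + 1):
                metas.append(
                    SampleMeta(
                        sample_id=f"cal-{matrix}-L{level:g}-r{rep}",
                        role=role, matrix=matrix, nominal_conc=level,
                        day=1, replicate=rep,
                    )
                )
    for day in range(1, design.days + 1):
        for level in design.fortification_levels:
            for rep in range(1, design.replicates_per_level + 1):
                metas.append(
                    SampleMeta(
                        sample_id=f"fort-{design.validation_matrix}-L{level:g}-d{day}-r{rep}",
                        role=SampleRole.FORTIFIED, matrix=design.validation_matrix,
                        nominal_conc=level, day=day, replicate=rep,
                    )
                )
        for rep in range(1, design.blanks_per_day + 1):
            metas.append(
                SampleMeta(
                    sample_id=f"blank-{design.validation_matrix}-d{day}-r{rep}",
                    role=SampleRole.BLANK, matrix=design.validation_matrix,
                    nominal_conc=0.0, day=day, replicate=rep,
                )
            )

    injections: list[InjectionRecord] = []
    for meta in metas:
        for rec in registry:
            injections.extend(model.records_for(rec, meta, design))
    return injections, metas


def simulate_monitoring(
    registry: Sequence[CompoundRecord],
    truth: GroundTruthLedger,
    n_samples: int,
    prevalence: Mapping[str, float] | float,
    conc_distribution: Mapping[str, tuple[float, float]] | tuple[float, float] = (3.0, 0.8),
    *,
    matrix: str = "RFNo",
    seed: int | None = None,
    design: DesignSpec | None = None,
    units: ConcentrationUnitsPolicy | None = None,
) -> tuple[list[InjectionRecord], list[SampleMeta]]:
    """Generate a routine-monitoring batch.

    Each of ``n_samples`` field samples carries each analyte independently
    with its prevalence; detected compounds get a lognormal soil
    concentration (``conc_distribution`` gives (mu, sigma) of log ng/g,
    per compound or globally). Non-detects contribute signal only through
    the compound's incurred blank level. IL-IS and the syringe standard are
    spiked into every sample at their nominal levels.
    """
    if n_samples < 1:
        raise RecordValidationError("n_samples must be >= 1")
    design = design or DesignSpec()
    units = units or ConcentrationUnitsPolicy()
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    analytes = [r for r in registry if r.is_analyte]

    def prev(name: str) -> float:
        p = prevalence if isinstance(prevalence, (int, float)) else prevalence.get(name, 0.0)
        if not 0.0 <= p <= 1.0:
            raise RecordValidationError(f"prevalence for {name!r} must be in [0, 1]")
        return float(p)

    def conc_params(name: str) -> tuple[float, float]:
        if isinstance(conc_distribution, tuple):
            return conc_distribution
        return conc_distribution[name]

    metas: list[SampleMeta] = []
    true_concs: dict[tuple[str, str], float] = {}
    for i in range(1, n_samples + 1):
        sid = f"mon-{matrix}-{i:04d}"
        metas.append(
            SampleMeta(sample_id=sid, role=SampleRole.MONITORING, matrix=matrix,
                       nominal_conc=0.0, day=1, replicate=i)
        )
        for rec in analytes:
            if rng.random() < prev(rec.name):
                mu, sigma = conc_params(rec.name)
                true_concs[(sid, rec.name)] = float(np.exp(rng.normal(mu, sigma)))

    model = _AreaModel(registry, truth, rng, 1, units)
    injections: list[InjectionRecord] = []
    for meta in metas:
        for rec in registry:
            spiked = true_concs.get((meta.sample_id, rec.name), 0.0)
            effective = dataclasses.replace(meta, nominal_conc=spiked)
            injections.extend(model.records_for(rec, effective, design))
    return injections, metas
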