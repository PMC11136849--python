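"""Domain types and file I/O for the residue-quantification pipeline.

The package operates on three tidy CSV tables:

``injections.csv``
    One row per measured peak: ``sample_id,compound,transition_role,area,rt,snr``
    (``snr`` may be empty). Areas are arbitrary detector units, retention
    times decimal minutes.
``samples.csv``
    One row per injected sample: ``sample_id,role,matrix,nominal_conc,day,replicate``.
    ``nominal_conc`` is ng/mL for calibration solutions and ng/g soil for
    fortified/monitoring samples; 0 for blanks.
``compounds.csv``
    The compound registry: ``name,category,ilis_group,si_ilis,expected_rt``.

All files are comma-separated UTF-8 with a dot decimal separator and one
header row. Compound names are matched case-insensitively after whitespace
normalization, so hand-edited registries with stray spaces still resolve.

Concentrations in the soil extract (ng/mL) and in the soil (ng/g) are
interconverted by a fixed extract-volume-per-mass policy, 1.0 mL/g by
default (5 g soil extracted into 5 mL solvent).
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "Category",
    "TransitionRole",
    "SampleRole",
    "CompoundRecord",
    "InjectionRecord",
    "SampleMeta",
    "ConcentrationUnitsPolicy",
    "Thresholds",
    "Config",
    "ResiduvalError",
    "SchemaError",
    "RecordValidationError",
    "UnknownCompoundError",
    "FixtureIntegrityError",
    "normalize_name",
    "read_compounds",
    "write_compounds",
    "read_injections",
    "write_injections",
    "read_samples",
    "write_samples",
    "load_registry",
    "load_table2_fixture",
    "load_config",
    "MATRICES",
    "SOIL_MATRICES",
]

# Soil matrices of the validation design: skeletic regosol (SR, the
# validation soil), rhodic ferralic nitisol organically (RFNo) and
# conventionally (RFNc) managed, xanthic ferralic nitisol (XFN) and
# dystric cambisol (DC). "solvent" is the ACN/FA calibration solution,
# "sand" a negative-control matrix used for batch blanks.
MATRICES = ("solvent", "SR", "RFNo", "RFNc", "XFN", "DC", "sand", "other")
SOIL_MATRICES = ("SR", "RFNo", "RFNc", "XFN", "DC")

_TABLE2_SHA256 = "73b5159ed52a0e4598fbbb7a6d593d2abc3f361f3230cc973fb3ab0aa1555375"


class ResiduvalError(Exception):
    """Base class for all package errors."""


class SchemaError(ResiduvalError):
    """A CSV/YAML file does not match the documented schema."""


class RecordValidationError(ResiduvalError):
    """A record violates a field invariant (e.g. negative peak area)."""


class UnknownCompoundError(ResiduvalError):
    """A compound name does not resolve against the registry."""


class FixtureIntegrityError(ResiduvalError):
    """A packaged data file fails its checksum."""


class Category(str, Enum):
    FUNGICIDE = "fungicide"
    HERBICIDE = "herbicide"
    INSECTICIDE_ACARICIDE = "insecticide_acaricide"
    TRANSFORMATION_PRODUCT = "transformation_product"
    INTERNAL_STANDARD = "internal_standard"
    SYRINGE_STANDARD = "syringe_standard"


class TransitionRole(str, Enum):
    QUANTIFIER = "quantifier"
    QUALIFIER = "qualifier"


class SampleRole(str, Enum):
    SOLVENT_CAL = "solvent_cal"
    MM_CAL = "mm_cal"
    BLANK = "blank"
    FORTIFIED = "fortified"
    MONITORING = "monitoring"


def normalize_name(name: str) -> str:
    """Collapse internal whitespace and casefold, for registry matching."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class CompoundRecord:
    """One analyte, transformation product, IL-IS or syringe standard.

    ``ilis_group`` names the isotope-labeled internal standard (IL-IS) used
    to quantify the compound (groups 1-10; 0 for the syringe standard, which
    is never quantified). ``si_ilis`` is True when the group's IL-IS is the
    structure-identical labeled analogue of this analyte.
    """

    name: str
    category: Category
    ilis_group: int
    si_ilis: bool
    expected_rt: float

    def __post_init__(self) -> None:
        if self.expected_rt <= 0:
            raise RecordValidationError(
                f"{self.name}: expected_rt must be > 0, got {self.expected_rt}"
            )
        if not (0 <= self.ilis_group <= 10):
            raise RecordValidationError(
                f"{self.name}: ilis_group must be in 0..10, got {self.ilis_group}"
            )

    @property
    def is_analyte(self) -> bool:
        return self.category not in (Category.INTERNAL_STANDARD, Category.SYRINGE_STANDARD)


@dataclass(frozen=True)
class InjectionRecord:
    """One measured peak for one compound-transition in one injection."""

    sample_id: str
    compound: str
    transition_role: TransitionRole
    area: float
    rt: float
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise RecordValidationError(
                f"sample {self.sample_id}, compound {self.compound}: "
                f"area must be >= 0, got {self.area}"
            )
        if self.rt <= 0:
            raise RecordValidationError(
                f"sample {self.sample_id}, compound {self.compound}: "
                f"rt must be > 0, got {self.rt}"
            )
        if self.snr is not None and self.snr < 0:
            raise RecordValidationError(
                f"sample {self.sample_id}, compound {self.compound}: "
                f"snr must be >= 0, got {self.snr}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one injected sample."""

    sample_id: str
    role: SampleRole
    matrix: str
    nominal_conc: float
    day: int = 1
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise RecordValidationError(
                f"sample {self.sample_id}: unknown matrix {self.matrix!r}"
            )
        if self.day < 1 or self.replicate < 1:
            raise RecordValidationError(
                f"sample {self.sample_id}: day and replicate must be >= 1"
            )
        if self.nominal_conc < 0:
            raise RecordValidationError(
                f"sample {self.sample_id}: nominal_conc must be >= 0"
            )


@dataclass(frozen=True)
class ConcentrationUnitsPolicy:
    """Conversion between extract (ng/mL) and soil (ng/g) concentrations.

    ``extract_volume_per_mass`` is the mL of final extract per g of soil
    taken; with 5 g soil in 5 mL solvent it is 1.0 and the two unit scales
    coincide numerically.
    """

    extract_volume_per_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.extract_volume_per_mass <= 0:
            raise RecordValidationError("extract_volume_per_mass must be > 0")

    def to_ng_per_g(self, conc_ng_ml: float) -> float:
        """Extract concentration (ng/mL) -> soil concentration (ng/g)."""
        return conc_ng_ml * self.extract_volume_per_mass

    def to_ng_per_ml(self, conc_ng_g: float) -> float:
        """Soil concentration (ng/g) -> extract concentration (ng/mL)."""
        return conc_ng_g / self.extract_volume_per_mass


@dataclass(frozen=True)
class Thresholds:
    """Acceptance thresholds of the validation and screening rules.

    Defaults follow the SANTE quality criteria applied to soils: repeatability
    and within-laboratory reproducibility RSD at most 20%, relative recovery
    70-120% (extended fit-for-purpose range 60-140%), calibration R^2 above
    0.99, LOQ at most 50 ng/g, matrix effect significant when |ME| exceeds
    20%, identification by retention time +/- 0.5 min and quantifier/qualifier
    ion ratio within +/- 50% (relative) of the calibration ratio, and blank
    signals no higher than 30% of the LOQ.
    """

    rsdr_max_pct: float = 20.0
    rsdR_max_pct: float = 20.0
    recovery_min_pct: float = 70.0
    recovery_max_pct: float = 120.0
    recovery_ext_min_pct: float = 60.0
    recovery_ext_max_pct: float = 140.0
    r_squared_min: float = 0.99
    loq_max_ng_g: float = 50.0
    me_significance_pct: float = 20.0
    snr_quantifier_min: float = 10.0
    snr_qualifier_min: float = 3.0
    rt_tolerance_min: float = 0.5
    ion_ratio_tolerance_pct: float = 50.0
    blank_max_fraction_of_loq: float = 0.3
    alpha: float = 0.05
    residue_sum_limits_ng_g: tuple[tuple[str, float], ...] = (
        ("czech", 100.0),
        ("netherlands", 70.0),
    )


@dataclass(frozen=True)
class Config:
    """Run configuration: units policy, thresholds and RNG seed."""

    units: ConcentrationUnitsPolicy = field(default_factory=ConcentrationUnitsPolicy)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0


def load_config(path: str | Path) -> Config:
    """Read a YAML config file; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    units = ConcentrationUnitsPolicy(**raw.get("units", {}))
    thr = raw.get("thresholds", {})
    if "residue_sum_limits_ng_g" in thr:
        thr = dict(thr)
        thr["residue_sum_limits_ng_g"] = tuple(
            (str(k), float(v)) for k, v in thr["residue_sum_limits_ng_g"].items()
        )
    thresholds = Thresholds(**thr)
    return Config(units=units, thresholds=thresholds, seed=int(raw.get("seed", 0)))


# ---------------------------------------------------------------------------
# CSV readers/writers
# ---------------------------------------------------------------------------

_INJECTION_COLUMNS = ["sample_id", "compound", "transition_role", "area", "rt", "snr"]
_SAMPLE_COLUMNS = ["sample_id", "role", "matrix", "nominal_conc", "day", "replicate"]
_COMPOUND_COLUMNS = ["name", "category", "ilis_group", "si_ilis", "expected_rt"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_compounds(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(path)
    _require_columns(df, _COMPOUND_COLUMNS, f"{path} (compounds)")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                name=str(row.name),
                category=Category(row.category),
                ilis_group=int(row.ilis_group),
                si_ilis=str(row.si_ilis).strip().lower() in ("true", "1", "yes"),
                expected_rt=float(row.expected_rt),
            )
        )
    return records


def write_compounds(records: Iterable[CompoundRecord], path: str | Path) -> None:
    rows = [
        (r.name, r.category.value, r.ilis_group, r.si_ilis, r.expected_rt)
        for r in records
    ]
    pd.DataFrame(rows, columns=_COMPOUND_COLUMNS).to_csv(path, index=False)


def registry_index(registry: Iterable[CompoundRecord]) -> dict[str, CompoundRecord]:
    """Normalized-name lookup table for a registry."""
    return {normalize_name(r.name): r for r in registry}


def read_injections(
    path: str | Path, registry: Iterable[CompoundRecord] | None = None
) -> list[InjectionRecord]:
    """Read an injections CSV, validating against a compound registry.

    Raises ``SchemaError`` for missing columns, ``RecordValidationError``
    (listing offending rows) for negative areas, and ``UnknownCompoundError``
    when a compound is absent from the registry.
    """
    df = pd.read_csv(path)
    _require_columns(df, _INJECTION_COLUMNS, f"{path} (injections)")
    bad = df.index[df["area"] < 0].tolist()
    if bad:
        raise RecordValidationError(
            f"{path}: negative area in rows (0-based, excluding header) {bad}"
        )
    index = registry_index(registry) if registry is not None else None
    records = []
    for row in df.itertuples(index=False):
        name = str(row.compound)
        if index is not None:
            rec = index.get(normalize_name(name))
            if rec is None:
                raise UnknownCompoundError(f"{path}: compound {name!r} not in registry")
            name = rec.name  # canonical spelling
        snr = None if pd.isna(row.snr) else float(row.snr)
        records.append(
            InjectionRecord(
                sample_id=str(row.sample_id),
                compound=name,
                transition_role=TransitionRole(row.transition_role),
                area=float(row.area),
                rt=float(row.rt),
                snr=snr,
            )
        )
    return records


def write_injections(records: Iterable[InjectionRecord], path: str | Path) -> None:
    rows = [
        (r.sample_id, r.compound, r.transition_role.value, r.area, r.rt,
         "" if r.snr is None else r.snr)
        for r in records
    ]
    pd.DataFrame(rows, columns=_INJECTION_COLUMNS).to_csv(path, index=False)


def read_samples(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    _require_columns(df, _SAMPLE_COLUMNS, f"{path} (samples)")
    return [
        SampleMeta(
            sample_id=str(row.sample_id),
            role=SampleRole(row.role),
            matrix=str(row.matrix),
            nominal_conc=float(row.nominal_conc),
            day=int(row.day),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]


def write_samples(records: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        (r.sample_id, r.role.value, r.matrix, r.nominal_conc, r.day, r.replicate)
        for r in records
    ]
    pd.DataFrame(rows, columns=_SAMPLE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _data_text(filename: str) -> str:
    return resources.files("residuval.data").joinpath(filename).read_text()


def load_registry() -> list[CompoundRecord]:
    """The default compound registry: 38 analytes, 10 IL-IS, one syringe standard.

    This is a synthetic reconstruction of the method's compound list: analyte
    names, pesticide types and IL-IS group numbers follow the published
    validation table, while the structure-identical flags, the IL-IS identities
    and the expected retention times are plausible reconstructions (the
    original instrument acquisition table is not public). Eleven analytes are
    flagged as having a structure-identical IL-IS; the group-4 IL-IS serves
    two metribuzin transformation products at once.
    """
    df = pd.read_csv(io.StringIO(_data_text("registry_synthetic.csv")))
    return [
        CompoundRecord(
            name=str(r.name),
            category=Category(r.category),
            ilis_group=int(r.ilis_group),
            si_ilis=bool(r.si_ilis),
            expected_rt=float(r.expected_rt),
        )
        for r in df.itertuples(index=False)
    ]


def load_table2_fixture() -> "list":
    """The published per-compound validation figures of merit.

    Returns one :class:`residuval.validation.ValidationRecord` per analyte
    (38 rows): RSDr and RSDR at the three fortification levels (10/25/50
    ng/g), relative recovery at each level, LOQ (ng/g) and calibration R^2,
    exactly as printed. The file checksum is verified on every load.
    """
    from .validation import ValidationRecord  # deferred: validation imports core_io

    text = _data_text("table2.csv")
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE2_SHA256:
        raise FixtureIntegrityError(
            f"table2.csv checksum mismatch: {digest} != {_TABLE2_SHA256}"
        )
    df = pd.read_csv(io.StringIO(text))
    records = []
    for r in df.itertuples(index=False):
        records.append(
            ValidationRecord(
                compound=str(r.analyte),
                category=Category(r.category),
                ilis_group=int(r.ilis_group),
                rsd_r={10.0: r.rsdr_10, 25.0: r.rsdr_25, 50.0: r.rsdr_50},
                rsd_R={10.0: r.rsdR_10, 25.0: r.rsdR_25, 50.0: r.rsdR_50},
                relative_recovery={
                    10.0: r.recovery_10, 25.0: r.recovery_25, 50.0: r.recovery_50
                },
                loq=float(r.loq),
                r_squared=float(r.r_squared),
            )
        )
    return records


def table2_dataframe() -> pd.DataFrame:
    """The validation-table fixture as a raw DataFrame (printed columns)."""
    text = _data_text("table2.csv")
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE2_SHA256:
        raise FixtureIntegrityError("table2.csv checksum mismatch")
    return pd.read_csv(io.StringIO(text))
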