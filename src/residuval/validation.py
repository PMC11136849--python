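"""Method-validation statistics: precision, trueness, LOQ, linearity, Horwitz.

The validation design fortifies the validation soil at three levels (10, 25,
50 ng/g) in quadruplicate on each of three days. Repeatability (RSDr) is the
relative standard deviation of one day's quadruplicates; within-laboratory
reproducibility (RSDR) pools all days' replicates (12 values in the
reference design). Trueness is expressed as relative recovery — quantified
over spiked concentration, x100 — and extraction performance as the absolute
recovery of each IL-IS against the syringe standard. The LOQ is the lowest
calibration level whose quantifier transition has S/N > 10 and qualifier
S/N > 3 (strict inequalities). The Horwitz function

    RSD_bl (%) = 2^(1 - 0.5 * log10(C)),   C the dimensionless mass fraction

gives the expected between-laboratory precision, with within-laboratory RSD
taken as two-thirds of it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    Category,
    CompoundRecord,
    ConcentrationUnitsPolicy,
    InjectionRecord,
    ResiduvalError,
    SampleMeta,
    SampleRole,
    Thresholds,
    TransitionRole,
)
from .calibration import (
    CalibrationCurve,
    CalibrationMode,
    build_response_points,
    fit_curve,
    ilis_by_group,
    internal_response,
    quantifier_areas,
    quantify,
)

__all__ = [
    "ValidationRecord",
    "RecoveryRecord",
    "HorwitzBound",
    "rsd",
    "precision_table",
    "relative_recovery",
    "absolute_recovery",
    "horwitz",
    "mass_fraction",
    "determine_loq",
    "quantify_fortified",
    "build_validation_report",
    "summarize_report",
    "InsufficientReplicatesError",
    "UndefinedRSDError",
    "DesignIncompletenessError",
    "NoLOQError",
]

FORTIFICATION_LEVELS = (10.0, 25.0, 50.0)


class InsufficientReplicatesError(ResiduvalError):
    """Fewer than two values for a dispersion statistic."""


class UndefinedRSDError(ResiduvalError):
    """The mean is zero; an RSD cannot be formed."""


class DesignIncompletenessError(ResiduvalError):
    """A (compound, level, day) cell of the validation design is missing."""


class NoLOQError(ResiduvalError):
    """No calibration level satisfies both S/N criteria."""


@dataclass(frozen=True)
class ValidationRecord:
    """One analyte's validation figures of merit (one table row).

    Per-level dictionaries are keyed by fortification level in ng/g.
    ``flags`` holds the names of the criteria the compound passes.
    """

    compound: str
    category: Category
    ilis_group: int
    rsd_r: Mapping[float, float]
    rsd_R: Mapping[float, float]
    relative_recovery: Mapping[float, float]
    loq: float
    r_squared: float
    flags: frozenset[str] = frozenset()

    @property
    def mean_relative_recovery(self) -> float:
        return float(np.mean(list(self.relative_recovery.values())))


@dataclass(frozen=True)
class RecoveryRecord:
    """One recovery figure: absolute (an IL-IS vs the syringe standard) or
    relative (an analyte's quantified vs spiked concentration)."""

    compound: str
    kind: str  # absolute | relative
    level: float
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ResiduvalError("recovery cannot be negative")
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"unknown recovery kind {self.kind!r}")


@dataclass(frozen=True)
class HorwitzBound:
    concentration: float  # dimensionless mass fraction
    rsd_bl: float  # between-laboratory RSD, percent
    rsd_wl: float  # within-laboratory RSD, percent (2/3 of rsd_bl)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation: 100 * sample SD (n-1) / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 values for an RSD, got {values.size}"
        )
    mean = values.mean()
    if mean == 0:
        raise UndefinedRSDError("mean is zero; RSD undefined")
    return float(100.0 * values.std(ddof=1) / mean)


def relative_recovery(measured: float, spiked: float) -> float:
    """Trueness: 100 * measured / spiked concentration."""
    if spiked <= 0:
        raise ResiduvalError(f"spiked concentration must be > 0, got {spiked}")
    return 100.0 * measured / spiked


def absolute_recovery(area_ilis: float, area_tpp: float, cal_ratio: float) -> float:
    """Extraction efficiency of an IL-IS spiked before extraction.

    The IL-IS/syringe-standard area ratio in the processed sample is
    referenced to the same ratio in the calibration standards (where nothing
    was extracted), so losses during extraction and clean-up show up as a
    recovery below 100%.
    """
    if area_tpp <= 0:
        raise ResiduvalError("syringe-standard area must be > 0")
    if cal_ratio <= 0:
        raise ResiduvalError("calibration area ratio must be > 0")
    return 100.0 * (area_ilis / area_tpp) / cal_ratio


def mass_fraction(conc_ng_g: float) -> float:
    """ng/g soil -> dimensionless mass fraction (1 ng/g = 1e-9)."""
    return conc_ng_g * 1e-9


def horwitz(concentration: float) -> HorwitzBound:
    """Horwitz precision bound at a dimensionless mass fraction C."""
    if concentration <= 0:
        raise ResiduvalError(f"concentration must be > 0, got {concentration}")
    rsd_bl = 2.0 ** (1.0 - 0.5 * math.log10(concentration))
    return HorwitzBound(concentration, float(rsd_bl), float(rsd_bl * 2.0 / 3.0))


def precision_table(
    concentrations: pd.DataFrame,
    repeatability_day: int | None = None,
) -> pd.DataFrame:
    """RSDr and RSDR per (compound, level) from quantified fortified samples.

    ``concentrations`` needs columns compound, level, day, replicate, conc.
    RSDr is the RSD of the designated day's replicates (the first day
    present, unless ``repeatability_day`` is given); RSDR is the RSD pooled
    over all days' replicates. Every (level, day) cell must hold at least
    two replicates.
    """
    required = {"compound", "level", "day", "replicate", "conc"}
    if not required.issubset(concentrations.columns):
        raise DesignIncompletenessError(
            f"missing columns {sorted(required - set(concentrations.columns))}"
        )
    rows = []
    for (compound, level), group in concentrations.groupby(["compound", "level"]):
        days = sorted(group["day"].unique())
        for day in days:
            if (group["day"] == day).sum() < 2:
                raise DesignIncompletenessError(
                    f"{compound} at {level}: day {day} has < 2 replicates"
                )
        r_day = repeatability_day if repeatability_day is not None else days[0]
        if r_day not in days:
            raise DesignIncompletenessError(
                f"{compound} at {level}: no replicates on day {r_day}"
            )
        within = group.loc[group["day"] == r_day, "conc"].to_numpy()
        rows.append(
            {
                "compound": compound,
                "level": level,
                "rsd_r": rsd(within),
                "rsd_R": rsd(group["conc"].to_numpy()) if len(days) > 1 else rsd(within),
                "n_days": len(days),
            }
        )
    return pd.DataFrame(rows)


def determine_loq(
    dilution_series: Sequence[tuple[float, float, float]],
    units: ConcentrationUnitsPolicy | None = None,
    *,
    snr_quant_min: float = 10.0,
    snr_qual_min: float = 3.0,
) -> float:
    """LOQ (ng/g): lowest level whose quantifier S/N exceeds 10 and
    qualifier S/N exceeds 3, both strictly.

    ``dilution_series`` holds (level_ng_ml, snr_quantifier, snr_qualifier)
    tuples; levels are sorted before scanning.
    """
    units = units or ConcentrationUnitsPolicy()
    for level, snr_q, snr_ql in sorted(dilution_series):
        if snr_q > snr_quant_min and snr_ql > snr_qual_min:
            return units.to_ng_per_g(level)
    raise NoLOQError("no level meets both S/N criteria; compound not quantifiable")


# ---------------------------------------------------------------------------
# Report pipeline
# ---------------------------------------------------------------------------


def quantify_fortified(
    injections: Sequence[InjectionRecord],
    samples: Sequence[SampleMeta],
    registry: Sequence[CompoundRecord],
    curves: Mapping[tuple[str, str], CalibrationCurve],
    *,
    mode: CalibrationMode = CalibrationMode.INTERNAL,
    units: ConcentrationUnitsPolicy | None = None,
) -> pd.DataFrame:
    """Back-calculate every fortified sample against its matrix's curve.

    Returns a tidy frame (compound, matrix, level, day, replicate, conc).
    """
    units = units or ConcentrationUnitsPolicy()
    areas = quantifier_areas(injections)
    groups = ilis_by_group(registry)
    rows = []
    for meta in samples:
        if meta.role is not SampleRole.FORTIFIED:
            continue
        for rec in registry:
            if not rec.is_analyte:
                continue
            curve = curves.get((rec.name, meta.matrix))
            if curve is None:
                continue
            inj = areas.get((meta.sample_id, rec.name))
            if inj is None:
                continue
            if mode is CalibrationMode.INTERNAL:
                ilis = groups[rec.ilis_group]
                ilis_inj = areas[(meta.sample_id, ilis.name)]
                response = internal_response(inj.area, ilis_inj.area, meta.sample_id)
            else:
                response = inj.area
            q = quantify(curve, response, units)
            rows.append(
                {
                    "compound": rec.name,
                    "matrix": meta.matrix,
                    "level": meta.nominal_conc,
                    "day": meta.day,
                    "replicate": meta.replicate,
                    "conc": q.conc_ng_g,
                    "clipped": q.clipped,
                }
            )
    return pd.DataFrame(rows)


def _snr_series(
    injections: Sequence[InjectionRecord],
    samples: Sequence[SampleMeta],
    compound: str,
    matrix: str,
) -> list[tuple[float, float, float]]:
    """Mean quantifier/qualifier S/N per matrix-matched calibration level."""
    meta_by_id = {m.sample_id: m for m in samples}
    per_level: dict[float, dict[str, list[float]]] = {}
    for inj in injections:
        if inj.compound != compound or inj.snr is None:
            continue
        meta = meta_by_id.get(inj.sample_id)
        if meta is None or meta.role is not SampleRole.MM_CAL or meta.matrix != matrix:
            continue
        slot = per_level.setdefault(meta.nominal_conc, {"quant": [], "qual": []})
        key = "quant" if inj.transition_role is TransitionRole.QUANTIFIER else "qual"
        slot[key].append(inj.snr)
    return [
        (level, float(np.mean(v["quant"])), float(np.mean(v["qual"])))
        for level, v in sorted(per_level.items())
        if v["quant"] and v["qual"]
    ]


def compute_flags(
    record: "ValidationRecord", thresholds: Thresholds | None = None
) -> frozenset[str]:
    """Compliance flags for one validation row.

    rsdr_pass / rsdR_pass require every level to meet the 20% criterion;
    recovery_pass requires every level within 70-120% (extended: 60-140%);
    linearity_pass is R^2 > 0.99 and loq_pass LOQ <= 50 ng/g.
    """
    thr = thresholds or Thresholds()
    flags = set()
    if all(v <= thr.rsdr_max_pct for v in record.rsd_r.values()):
        flags.add("rsdr_pass")
    if all(v <= thr.rsdR_max_pct for v in record.rsd_R.values()):
        flags.add("rsdR_pass")
    recs = record.relative_recovery.values()
    if all(thr.recovery_min_pct <= v <= thr.recovery_max_pct for v in recs):
        flags.add("recovery_pass")
    if all(thr.recovery_ext_min_pct <= v <= thr.recovery_ext_max_pct for v in recs):
        flags.add("recovery_extended_pass")
    if record.r_squared > thr.r_squared_min:
        flags.add("linearity_pass")
    if record.loq <= thr.loq_max_ng_g:
        flags.add("loq_pass")
    return frozenset(flags)


def build_validation_report(
    injections: Sequence[InjectionRecord],
    samples: Sequence[SampleMeta],
    registry: Sequence[CompoundRecord],
    *,
    validation_matrix: str = "SR",
    mode: CalibrationMode = CalibrationMode.INTERNAL,
    thresholds: Thresholds | None = None,
    units: ConcentrationUnitsPolicy | None = None,
    repeatability_day: int | None = None,
) -> list[ValidationRecord]:
    """Full validation report for one matrix: one record per analyte.

    Fits matrix-matched curves, quantifies the fortified replicates,
    derives RSDr/RSDR and relative recovery per fortification level, the
    LOQ from the calibration S/N series, and the calibration R^2, then
    attaches compliance flags.
    """
    thr = thresholds or Thresholds()
    units = units or ConcentrationUnitsPolicy()
    points = build_response_points(injections, samples, registry, mode)
    curves = {
        key: fit_curve(pts, key[0], key[1], mode)
        for key, pts in points.items()
        if key[1] == validation_matrix
    }
    concs = quantify_fortified(
        injections, samples, registry, curves, mode=mode, units=units
    )
    concs = concs[concs["matrix"] == validation_matrix]
    if concs.empty:
        raise DesignIncompletenessError(
            f"no fortified samples in matrix {validation_matrix!r}"
        )
    prec = precision_table(concs, repeatability_day=repeatability_day)

    records = []
    for rec in registry:
        if not rec.is_analyte:
            continue
        curve = curves.get((rec.name, validation_matrix))
        if curve is None:
            continue
        mine = concs[concs["compound"] == rec.name]
        levels = sorted(mine["level"].unique())
        rec_by_level = {
            float(lv): float(
                np.mean(
                    [
                        relative_recovery(c, lv)
                        for c in mine.loc[mine["level"] == lv, "conc"]
                    ]
                )
            )
            for lv in levels
        }
        p = prec[prec["compound"] == rec.name].set_index("level")
        loq = determine_loq(
            _snr_series(injections, samples, rec.name, validation_matrix),
            units,
            snr_quant_min=thr.snr_quantifier_min,
            snr_qual_min=thr.snr_qualifier_min,
        )
        row = ValidationRecord(
            compound=rec.name,
            category=rec.category,
            ilis_group=rec.ilis_group,
            rsd_r={float(lv): float(p.loc[lv, "rsd_r"]) for lv in levels},
            rsd_R={float(lv): float(p.loc[lv, "rsd_R"]) for lv in levels},
            relative_recovery=rec_by_level,
            loq=loq,
            r_squared=curve.r_squared,
        )
        records.append(dataclasses.replace(row, flags=compute_flags(row, thr)))
    return records


def summarize_report(records: Sequence[ValidationRecord]) -> pd.DataFrame:
    """Mean/Min/Max summary rows over the per-compound validation records."""
    if not records:
        raise DesignIncompletenessError("no validation records to summarize")
    levels = sorted({lv for r in records for lv in r.rsd_r})
    cols: dict[str, np.ndarray] = {}
    for lv in levels:
        cols[f"rsdr_{lv:g}"] = np.array([r.rsd_r[lv] for r in records])
        cols[f"rsdR_{lv:g}"] = np.array([r.rsd_R[lv] for r in records])
        cols[f"recovery_{lv:g}"] = np.array([r.relative_recovery[lv] for r in records])
    cols["loq"] = np.array([r.loq for r in records])
    cols["r_squared"] = np.array([r.r_squared for r in records])
    return pd.DataFrame(
        {
            name: {"mean": v.mean(), "min": v.min(), "max": v.max()}
            for name, v in cols.items()
        }
    )
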