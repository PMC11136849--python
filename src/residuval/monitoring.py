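"""Routine-monitoring screen: identification, censoring, occurrence, exceedance.

A residue is reported in a monitoring sample only when it passes four
checks: retention time within +/- 0.5 min of the expected value; observed
quantifier/qualifier ion ratio within +/- 50% (relative) of the calibration
ratio; back-calculated concentration at or above the compound's LOQ; and —
for compounds with known incurred blank contamination — a concentration
strictly above every concurrently processed blank (blank-referenced
reporting, the metribuzin-DADK rule). Batch summaries count detection
frequencies, per-sample residue co-occurrence, and the fraction of samples
whose summed residues exceed regulatory screening limits (strict
inequality), with censored compounds contributing zero to the sums.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
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
    ilis_by_group,
    internal_response,
    quantifier_areas,
    quantify,
)

__all__ = [
    "ScreenResult",
    "OccurrenceSummary",
    "ExceedanceReport",
    "selectivity_check",
    "specificity_check",
    "blank_referenced_report",
    "screen_batch",
    "summarize_occurrence",
    "batch_statistics",
    "exceedance",
    "IncompleteIdentificationError",
    "MissingBlankError",
]


class IncompleteIdentificationError(ResiduvalError):
    """The qualifier transition needed for identification is missing."""


class MissingBlankError(ResiduvalError):
    """A blank-flagged compound has no batch blanks to reference."""


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the four-step screen for one (sample, compound)."""

    sample_id: str
    compound: str
    rt_ok: bool
    ion_ratio_ok: bool
    above_loq: bool
    blank_ok: bool
    conc_ng_g: float  # back-calculated, before censoring
    reported_conc: float | None  # present only when all checks pass
    censor_reason: str | None = None


@dataclass(frozen=True)
class OccurrenceSummary:
    compound: str
    n_samples: int
    n_detects: int
    detection_frequency: float  # percent
    median_conc: float | None  # over detects, ng/g dw
    max_conc: float | None


@dataclass(frozen=True)
class ExceedanceReport:
    """Per-threshold counts of samples whose residue sum exceeds a limit."""

    residue_sums: Mapping[str, float]  # sample_id -> ng/g dw
    thresholds: Mapping[str, float]
    n_exceeding: Mapping[str, int]
    fraction_exceeding: Mapping[str, float]


def selectivity_check(
    quant: InjectionRecord,
    qual: InjectionRecord | None,
    expected_rt: float,
    cal_ion_ratio: float,
    rt_tol: float = 0.5,
    ratio_tol_pct: float = 50.0,
) -> tuple[bool, bool]:
    """Identify a peak by retention time and ion ratio.

    ``rt_ok`` when |rt - expected| <= rt_tol (minutes); ``ion_ratio_ok`` when
    the observed qualifier/quantifier ratio lies within cal_ion_ratio *
    (1 +/- ratio_tol_pct/100), boundaries inclusive.
    """
    if qual is None:
        raise IncompleteIdentificationError(
            f"sample {quant.sample_id}, {quant.compound}: qualifier transition missing"
        )
    rt_ok = abs(quant.rt - expected_rt) <= rt_tol
    if quant.area <= 0:
        return rt_ok, False
    observed = qual.area / quant.area
    tol = ratio_tol_pct / 100.0
    ion_ratio_ok = (
        cal_ion_ratio * (1.0 - tol) <= observed <= cal_ion_ratio * (1.0 + tol)
    )
    return rt_ok, bool(ion_ratio_ok)


def specificity_check(blank_conc: float, loq: float) -> bool:
    """Blank signal acceptable iff it does not exceed 30% of the LOQ."""
    if loq <= 0:
        raise ResiduvalError(f"loq must be > 0, got {loq}")
    return blank_conc <= 0.3 * loq


def blank_referenced_report(
    conc: float, batch_blank_concs: Sequence[float]
) -> tuple[float | None, str | None]:
    """Report ``conc`` only when strictly above every batch blank.

    Returns (reported, None) or (None, reason) when censored.
    """
    if len(batch_blank_concs) == 0:
        raise MissingBlankError("no batch blanks available for a flagged compound")
    ceiling = max(batch_blank_concs)
    if conc > ceiling:
        return conc, None
    return None, f"not above batch blanks (max blank {ceiling:g} ng/g)"


def _calibration_ion_ratios(
    injections: Sequence[InjectionRecord], samples: Sequence[SampleMeta]
) -> dict[str, float]:
    """Mean qualifier/quantifier area ratio per compound over calibration runs."""
    meta = {m.sample_id: m for m in samples}
    cal_roles = (SampleRole.SOLVENT_CAL, SampleRole.MM_CAL)
    by_key: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    for inj in injections:
        m = meta.get(inj.sample_id)
        if m is None or m.role not in cal_roles or m.nominal_conc == 0:
            continue
        by_key[(inj.sample_id, inj.compound)][inj.transition_role.value] = inj.area
    ratios: dict[str, list[float]] = defaultdict(list)
    for (sid, compound), areas in by_key.items():
        if areas.get("quantifier", 0) > 0 and "qualifier" in areas:
            ratios[compound].append(areas["qualifier"] / areas["quantifier"])
    return {c: float(np.mean(v)) for c, v in ratios.items()}


def screen_batch(
    injections: Sequence[InjectionRecord],
    samples: Sequence[SampleMeta],
    registry: Sequence[CompoundRecord],
    curves: Mapping[tuple[str, str], CalibrationCurve],
    loqs: Mapping[str, float],
    *,
    mode: CalibrationMode = CalibrationMode.INTERNAL,
    thresholds: Thresholds | None = None,
    units: ConcentrationUnitsPolicy | None = None,
    blank_flagged: Iterable[str] = (),
    cal_ion_ratios: Mapping[str, float] | None = None,
) -> list[ScreenResult]:
    """Run the full QA/QC screen over a monitoring batch.

    ``curves`` must contain a curve for each (compound, matrix) to be
    quantified; ``loqs`` maps compound -> LOQ in ng/g. Compounds listed in
    ``blank_flagged`` are additionally censored against the batch's blank
    samples (quantified with the same curves). Calibration ion ratios are
    taken from ``cal_ion_ratios`` or derived from calibration injections
    present in the batch.
    """
    thr = thresholds or Thresholds()
    units = units or ConcentrationUnitsPolicy()
    blank_flagged = set(blank_flagged)
    if cal_ion_ratios is None:
        cal_ion_ratios = _calibration_ion_ratios(injections, samples)
    areas = quantifier_areas(injections)
    qual_areas = {
        (r.sample_id, r.compound): r
        for r in injections
        if r.transition_role is TransitionRole.QUALIFIER
    }
    groups = ilis_by_group(registry)
    reg = {r.name: r for r in registry}

    def back_calc(meta: SampleMeta, compound: str) -> float | None:
        curve = curves.get((compound, meta.matrix))
        inj = areas.get((meta.sample_id, compound))
        if curve is None or inj is None:
            return None
        if mode is CalibrationMode.INTERNAL:
            ilis = groups[reg[compound].ilis_group]
            ilis_inj = areas.get((meta.sample_id, ilis.name))
            if ilis_inj is None:
                raise IncompleteIdentificationError(
                    f"sample {meta.sample_id}: IL-IS {ilis.name!r} missing"
                )
            response = internal_response(inj.area, ilis_inj.area, meta.sample_id)
        else:
            response = inj.area
        return quantify(curve, response, units).conc_ng_g

    # quantify batch blanks once, for the blank-referenced rule
    blank_concs: dict[str, list[float]] = defaultdict(list)
    for meta in samples:
        if meta.role is SampleRole.BLANK:
            for name in blank_flagged:
                conc = back_calc(meta, name)
                if conc is not None:
                    blank_concs[name].append(conc)

    results: list[ScreenResult] = []
    for meta in samples:
        if meta.role is not SampleRole.MONITORING:
            continue
        for rec in registry:
            if not rec.is_analyte:
                continue
            conc = back_calc(meta, rec.name)
            inj = areas.get((meta.sample_id, rec.name))
            if conc is None or inj is None:
                continue
            qual = qual_areas.get((meta.sample_id, rec.name))
            rt_ok, ratio_ok = selectivity_check(
                inj,
                qual,
                rec.expected_rt,
                cal_ion_ratios.get(rec.name, 0.0),
                rt_tol=thr.rt_tolerance_min,
                ratio_tol_pct=thr.ion_ratio_tolerance_pct,
            )
            loq = loqs.get(rec.name)
            above_loq = loq is not None and conc >= loq
            blank_ok = True
            reason: str | None = None
            if rec.name in blank_flagged:
                reported, reason = blank_referenced_report(
                    conc, blank_concs.get(rec.name, [])
                )
                blank_ok = reported is not None
            passed = rt_ok and ratio_ok and above_loq and blank_ok
            if not passed and reason is None:
                reason = (
                    "rt outside window" if not rt_ok
                    else "ion ratio outside tolerance" if not ratio_ok
                    else "below LOQ"
                )
            results.append(
                ScreenResult(
                    sample_id=meta.sample_id,
                    compound=rec.name,
                    rt_ok=rt_ok,
                    ion_ratio_ok=ratio_ok,
                    above_loq=above_loq,
                    blank_ok=blank_ok,
                    conc_ng_g=conc,
                    reported_conc=conc if passed else None,
                    censor_reason=None if passed else reason,
                )
            )
    return results


def summarize_occurrence(
    screened: Sequence[ScreenResult],
) -> list[OccurrenceSummary]:
    """Per-compound detection frequency and concentration range over detects."""
    if not screened:
        raise ResiduvalError("empty batch")
    n_samples = len({r.sample_id for r in screened})
    by_compound: dict[str, list[float]] = defaultdict(list)
    compounds = sorted({r.compound for r in screened})
    for r in screened:
        if r.reported_conc is not None:
            by_compound[r.compound].append(r.reported_conc)
    out = []
    for compound in compounds:
        detects = by_compound.get(compound, [])
        out.append(
            OccurrenceSummary(
                compound=compound,
                n_samples=n_samples,
                n_detects=len(detects),
                detection_frequency=100.0 * len(detects) / n_samples,
                median_conc=float(np.median(detects)) if detects else None,
                max_conc=float(np.max(detects)) if detects else None,
            )
        )
    return out


def batch_statistics(screened: Sequence[ScreenResult], k: int = 3) -> dict:
    """Batch-level occurrence statistics.

    Returns the fraction of samples with at least one reported residue, the
    per-sample detect counts, and the fraction with ``k`` or more
    co-occurring residues.
    """
    if not screened:
        raise ResiduvalError("empty batch")
    counts: dict[str, int] = defaultdict(int)
    for r in screened:
        counts.setdefault(r.sample_id, 0)
        if r.reported_conc is not None:
            counts[r.sample_id] += 1
    values = np.array(list(counts.values()))
    return {
        "n_samples": len(counts),
        "fraction_with_detect": float(np.mean(values >= 1)),
        "fraction_cooccurrence_ge_k": float(np.mean(values >= k)),
        "k": k,
        "detect_counts": dict(counts),
    }


def exceedance(
    screened: Sequence[ScreenResult],
    thresholds: Mapping[str, float] | None = None,
) -> ExceedanceReport:
    """Sum reported residues per sample and compare with screening limits.

    Censored compounds contribute zero. Exceedance is strict: a sum exactly
    equal to a limit does not exceed it.
    """
    limits = dict(thresholds) if thresholds is not None else dict(
        Thresholds().residue_sum_limits_ng_g
    )
    if any(v <= 0 for v in limits.values()):
        raise ResiduvalError("thresholds must be > 0")
    sums: dict[str, float] = defaultdict(float)
    for r in screened:
        sums.setdefault(r.sample_id, 0.0)
        if r.reported_conc is not None:
            sums[r.sample_id] += r.reported_conc
    n = len(sums)
    n_exc = {name: sum(1 for s in sums.values() if s > lim) for name, lim in limits.items()}
    return ExceedanceReport(
        residue_sums=dict(sums),
        thresholds=limits,
        n_exceeding=n_exc,
        fraction_exceeding={name: (c / n if n else 0.0) for name, c in n_exc.items()},
    )
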