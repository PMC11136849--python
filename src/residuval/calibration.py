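"""Matrix-matched calibration: response points, OLS fits, quantification.

Curves are ordinary least squares with an intercept — never forced through
the origin — fitted on individual response points (replicated levels enter
as separate points, preserving the information in the slope variance). The
zero-concentration level never enters a fit. In external mode the response
is the quantifier peak area; in internal mode it is the quantifier area
divided by the area of the IL-IS assigned through the compound's IL-IS
group, which is what cancels matrix effects for structure-identical pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import (
    Category,
    CompoundRecord,
    ConcentrationUnitsPolicy,
    InjectionRecord,
    ResiduvalError,
    SampleMeta,
    SampleRole,
    TransitionRole,
    registry_index,
)

__all__ = [
    "CalibrationMode",
    "ResponsePoint",
    "CalibrationCurve",
    "QuantifiedValue",
    "build_response_points",
    "fit_curve",
    "fit_all_curves",
    "quantify",
    "PairingError",
    "InsufficientDataError",
    "DegenerateDesignError",
    "UnusableCurveError",
]


class PairingError(ResiduvalError):
    """An IL-IS area needed for normalization is missing or zero."""


class InsufficientDataError(ResiduvalError):
    """Fewer than three distinct calibration levels."""


class DegenerateDesignError(ResiduvalError):
    """All calibration points sit at one level; the slope is undefined."""


class UnusableCurveError(ResiduvalError):
    """A curve with non-positive slope cannot be inverted."""


class CalibrationMode(str, Enum):
    EXTERNAL = "external"
    INTERNAL = "internal"


@dataclass(frozen=True)
class ResponsePoint:
    """One calibration point: level (ng/mL) and instrument response."""

    level: float
    response: float

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise InsufficientDataError("calibration level must be > 0 (0 is excluded)")
        if not np.isfinite(self.response):
            raise InsufficientDataError("response must be finite")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted line response = intercept + slope * level for one compound/matrix."""

    compound: str
    matrix: str
    mode: CalibrationMode
    slope: float
    intercept: float
    slope_variance: float
    r_squared: float
    n_points: int
    residual_sd: float


@dataclass(frozen=True)
class QuantifiedValue:
    """A back-calculated soil concentration; ``clipped`` marks a negative
    estimate that was truncated to zero (blanks with positive intercepts)."""

    conc_ng_g: float
    clipped: bool = False


_CAL_ROLES = (SampleRole.SOLVENT_CAL, SampleRole.MM_CAL)


def ilis_by_group(registry: Iterable[CompoundRecord]) -> dict[int, CompoundRecord]:
    out: dict[int, CompoundRecord] = {}
    for rec in registry:
        if rec.category is Category.INTERNAL_STANDARD:
            out[rec.ilis_group] = rec
    return out


def quantifier_areas(
    injections: Iterable[InjectionRecord],
) -> dict[tuple[str, str], InjectionRecord]:
    """Index quantifier records by (sample_id, compound)."""
    return {
        (r.sample_id, r.compound): r
        for r in injections
        if r.transition_role is TransitionRole.QUANTIFIER
    }


def internal_response(
    analyte_area: float, ilis_area: float, sample_id: str = "?"
) -> float:
    if ilis_area == 0:
        raise PairingError(f"sample {sample_id}: IL-IS area is zero, cannot normalize")
    return analyte_area / ilis_area


def build_response_points(
    injections: Sequence[InjectionRecord],
    samples: Sequence[SampleMeta],
    registry: Sequence[CompoundRecord],
    mode: CalibrationMode,
) -> dict[tuple[str, str], list[ResponsePoint]]:
    """Collect calibration points per (compound, matrix).

    External mode uses the quantifier area as response and ignores internal
    standards entirely; internal mode divides by the area of the group's
    IL-IS measured in the same injection.
    """
    mode = CalibrationMode(mode)
    areas = quantifier_areas(injections)
    groups = ilis_by_group(registry)
    points: dict[tuple[str, str], list[ResponsePoint]] = defaultdict(list)
    for meta in samples:
        if meta.role not in _CAL_ROLES or meta.nominal_conc == 0:
            continue
        for rec in registry:
            if not rec.is_analyte:
                continue
            inj = areas.get((meta.sample_id, rec.name))
            if inj is None:
                continue
            if mode is CalibrationMode.EXTERNAL:
                response = inj.area
            else:
                ilis = groups.get(rec.ilis_group)
                if ilis is None:
                    raise PairingError(
                        f"no IL-IS registered for group {rec.ilis_group} ({rec.name})"
                    )
                ilis_inj = areas.get((meta.sample_id, ilis.name))
                if ilis_inj is None:
                    raise PairingError(
                        f"sample {meta.sample_id}: missing IL-IS area for {ilis.name!r}"
                    )
                response = internal_response(inj.area, ilis_inj.area, meta.sample_id)
            points[(rec.name, meta.matrix)].append(
                ResponsePoint(level=meta.nominal_conc, response=response)
            )
    return dict(points)


def fit_curve(
    points: Sequence[ResponsePoint],
    compound: str = "",
    matrix: str = "",
    mode: CalibrationMode = CalibrationMode.INTERNAL,
) -> CalibrationCurve:
    """Unweighted OLS with intercept over the given points.

    The slope variance is the standard OLS variance of the slope estimator
    (squared standard error), and R^2 the squared Pearson correlation of
    response with level — equivalent to 1 - SSR/SST for an intercept model.
    """
    levels = np.array([p.level for p in points], dtype=float)
    responses = np.array([p.response for p in points], dtype=float)
    if len(np.unique(levels)) < 3:
        raise InsufficientDataError(
            f"{compound}/{matrix}: need >= 3 distinct levels, got {len(np.unique(levels))}"
        )
    if np.ptp(levels) == 0:
        raise DegenerateDesignError(f"{compound}/{matrix}: zero variance in levels")
    fit = stats.linregress(levels, responses)
    n = len(points)
    resid = responses - (fit.intercept + fit.slope * levels)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return CalibrationCurve(
        compound=compound,
        matrix=matrix,
        mode=CalibrationMode(mode),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_variance=float(fit.stderr**2),
        r_squared=float(fit.rvalue**2),
        n_points=n,
        residual_sd=residual_sd,
    )


def fit_all_curves(
    injections: Sequence[InjectionRecord],
    samples: Sequence[SampleMeta],
    registry: Sequence[CompoundRecord],
    mode: CalibrationMode,
) -> dict[tuple[str, str], CalibrationCurve]:
    """Fit one curve per (compound, matrix) present in the calibration data."""
    out = {}
    for (compound, matrix), pts in build_response_points(
        injections, samples, registry, mode
    ).items():
        out[(compound, matrix)] = fit_curve(pts, compound, matrix, mode)
    return out


def quantify(
    curve: CalibrationCurve,
    response: float,
    units: ConcentrationUnitsPolicy | None = None,
) -> QuantifiedValue:
    """Invert a calibration curve: response -> soil concentration (ng/g).

    Negative back-calculated concentrations (responses below the intercept,
    as happens for blanks) are clipped to zero and flagged rather than
    rejected.
    """
    if curve.slope <= 0:
        raise UnusableCurveError(
            f"{curve.compound}/{curve.matrix}: slope {curve.slope} is not positive"
        )
    units = units or ConcentrationUnitsPolicy()
    conc_extract = (response - curve.intercept) / curve.slope
    conc = units.to_ng_per_g(conc_extract)
    if conc < 0:
        return QuantifiedValue(0.0, clipped=True)
    return QuantifiedValue(float(conc), clipped=False)
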