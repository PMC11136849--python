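"""Matrix-effect quantification and slope-comparison testing.

The matrix effect of a compound in a soil is the percent deviation of its
matrix-matched calibration slope from the solvent slope,

    ME (%) = (slope_matrix / slope_solvent - 1) * 100,

computed either from external (raw-area) or internal (IL-IS-normalized)
curves. |ME| > 20% counts as significant: below -20% is suppression, above
+20% enhancement, and exactly +/-20% is non-significant (the inequality is
strict).

Slope equality between two matrices is tested with the two-sample statistic

    t = (b1 - b2) / sqrt(s2_b1 + s2_b2),   df = n1 + n2 - 4,

where s2_b are the OLS slope variances — an unequal-variance comparison of
two independently fitted regressions, with two parameters estimated per
regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import ResiduvalError
from .calibration import CalibrationCurve, CalibrationMode

__all__ = [
    "MEClass",
    "MatrixEffectResult",
    "SlopeComparison",
    "MESummary",
    "matrix_effect",
    "compare_slopes",
    "summarize_me",
    "matrix_effects_from_curves",
    "UndefinedMEError",
    "ComparisonError",
    "EmptyInputError",
]


class UndefinedMEError(ResiduvalError):
    """Solvent slope is not positive; the slope ratio is meaningless."""


class ComparisonError(ResiduvalError):
    """The two curves are not comparable (compound or mode differ)."""


class EmptyInputError(ResiduvalError):
    """A summary was requested over an empty collection."""


class MEClass(str, Enum):
    SUPPRESSION = "suppression"
    NONSIGNIFICANT = "nonsignificant"
    ENHANCEMENT = "enhancement"


@dataclass(frozen=True)
class MatrixEffectResult:
    compound: str
    matrix: str
    mode: CalibrationMode
    me_pct: float
    classification: MEClass


@dataclass(frozen=True)
class SlopeComparison:
    compound: str
    matrix_1: str
    matrix_2: str
    t_stat: float
    df: int
    p_value: float
    reject_h0: bool


@dataclass(frozen=True)
class MESummary:
    """Distribution summary of matrix effects for one matrix/mode/subgroup."""

    matrix: str
    mode: CalibrationMode
    subgroup: str  # all | si_ilis | nsi_ilis
    mean: float
    std: float
    q1: float
    median: float
    q3: float
    min: float
    max: float
    n_significant: int
    n_total: int


def matrix_effect(
    slope_mm: float,
    slope_solvent: float,
    mode: CalibrationMode = CalibrationMode.EXTERNAL,
    *,
    compound: str = "",
    matrix: str = "",
    significance_pct: float = 20.0,
) -> MatrixEffectResult:
    """Percent matrix effect from a matrix-matched and a solvent slope."""
    if slope_solvent <= 0:
        raise UndefinedMEError(
            f"{compound}/{matrix}: solvent slope must be > 0, got {slope_solvent}"
        )
    me = (slope_mm / slope_solvent - 1.0) * 100.0
    if me < -significance_pct:
        cls = MEClass.SUPPRESSION
    elif me > significance_pct:
        cls = MEClass.ENHANCEMENT
    else:
        cls = MEClass.NONSIGNIFICANT
    return MatrixEffectResult(compound, matrix, CalibrationMode(mode), float(me), cls)


def matrix_effects_from_curves(
    curves: Mapping[tuple[str, str], CalibrationCurve],
    solvent_matrix: str = "solvent",
    significance_pct: float = 20.0,
) -> list[MatrixEffectResult]:
    """Matrix effects for every (compound, soil) pair with a solvent curve."""
    results = []
    for (compound, matrix), curve in sorted(curves.items()):
        if matrix == solvent_matrix:
            continue
        solvent = curves.get((compound, solvent_matrix))
        if solvent is None:
            continue
        results.append(
            matrix_effect(
                curve.slope,
                solvent.slope,
                curve.mode,
                compound=compound,
                matrix=matrix,
                significance_pct=significance_pct,
            )
        )
    return results


def compare_slopes(
    c1: CalibrationCurve, c2: CalibrationCurve, alpha: float = 0.05
) -> SlopeComparison:
    """Test H0: the two curves have equal true slopes.

    Uses the unpooled slope-variance statistic with n1 + n2 - 4 degrees of
    freedom and a two-sided p-value. Antisymmetric in its arguments: swapping
    the curves negates t and leaves p unchanged.
    """
    if c1.compound != c2.compound or c1.mode != c2.mode:
        raise ComparisonError(
            f"cannot compare {c1.compound}/{c1.mode.value} with {c2.compound}/{c2.mode.value}"
        )
    if c1.n_points < 3 or c2.n_points < 3:
        raise ComparisonError("both curves need at least 3 points")
    df = c1.n_points + c2.n_points - 4
    diff = c1.slope - c2.slope
    denom = math.sqrt(c1.slope_variance + c2.slope_variance)
    if diff == 0:
        t = 0.0
    elif denom == 0:
        t = math.inf if diff > 0 else -math.inf
    else:
        t = diff / denom
    p = float(2.0 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return SlopeComparison(
        compound=c1.compound,
        matrix_1=c1.matrix,
        matrix_2=c2.matrix,
        t_stat=float(t),
        df=df,
        p_value=p,
        reject_h0=bool(p < alpha),
    )


def summarize_me(
    results: Sequence[MatrixEffectResult],
    subgroup: str = "all",
    si_flags: Mapping[str, bool] | None = None,
    *,
    matrix: str | None = None,
    significance_pct: float = 20.0,
) -> MESummary:
    """Distribution summary (mean, sample SD, quartiles, significance count).

    ``subgroup`` restricts to compounds with (si_ilis) or without (nsi_ilis)
    a structure-identical IL-IS; that requires ``si_flags`` mapping compound
    name to the flag. Quartiles use linear interpolation between order
    statistics. The sample SD uses the n-1 denominator and is NaN for a
    single value.
    """
    if subgroup not in ("all", "si_ilis", "nsi_ilis"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    selected = list(results)
    if matrix is not None:
        selected = [r for r in selected if r.matrix == matrix]
    if subgroup != "all":
        if si_flags is None:
            raise EmptyInputError("si_flags required for subgroup filtering")
        want = subgroup == "si_ilis"
        selected = [r for r in selected if si_flags.get(r.compound, False) == want]
    if not selected:
        raise EmptyInputError(f"no matrix-effect results in subgroup {subgroup!r}")
    values = np.array([r.me_pct for r in selected], dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    label = selected[0].matrix if matrix is None and len({r.matrix for r in selected}) == 1 \
        else (matrix or "all")
    return MESummary(
        matrix=label,
        mode=selected[0].mode,
        subgroup=subgroup,
        mean=float(values.mean()),
        std=float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        min=float(values.min()),
        max=float(values.max()),
        n_significant=int(np.sum(np.abs(values) > significance_pct)),
        n_total=len(values),
    )
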