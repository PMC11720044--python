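"""Age-dependent cancer risk as cumulative stem-cell divisions (SCD).

The risk level of an organ at a given age is modelled as the total number of
stem-cell divisions since the first precursor cell:

    SCD(age) = sum_{n=1..floor(log2 s)} 2^n  +  s * age * d_yr

The first term counts the divisions needed to build the fully developed
tissue of ``s`` stem cells by successive doubling (for s an exact power of
two it equals 2s - 2); the second counts ordinary turnover at ``d_yr``
divisions per stem cell per year.  Raw SCD spans roughly 1e8–1e12, so values
are scaled down by 1e9 by default.

SCD(age) is affine in age, so the fitted risk curve f1(x) reproduces it
exactly with a linear basis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .age_curves import AgeSeries, FittedCurve, fit_age_curve
from .errors import ValidationError

__all__ = [
    "OrganKinetics",
    "RiskCurve",
    "developmental_divisions",
    "scd_at_age",
    "risk_curve",
    "risk_curve_from_series",
]

DEFAULT_SCALE = 1e9


@dataclass(frozen=True)
class OrganKinetics:
    """Stem-cell kinetics of one organ: pool size s and divisions/year d_yr."""

    organ: str
    s: float
    d_yr: float

    def __post_init__(self):
        if self.s < 1:
            raise ValidationError("stem-cell count s must be >= 1")
        if self.d_yr < 0:
            raise ValidationError("d_yr must be nonnegative")


@dataclass(frozen=True)
class RiskCurve:
    """Fitted SCD-vs-age curve for one organ (the f1(x) of the ADOR models)."""

    organ: str
    scale: float
    curve: FittedCurve

    def __call__(self, ages):
        return self.curve(ages)


def developmental_divisions(s: float) -> float:
    """Divisions from one precursor cell to a developed organ of s stem cells.

    Computes sum_{n=1..floor(log2 s)} 2^n = 2^(floor(log2 s)+1) - 2.  For s an
    exact power of two this is exactly 2s - 2.  Organs with s < 2 are below
    the resolution of the doubling model; 0 is returned with a warning.
    """
    if s < 2:
        warnings.warn(
            f"stem-cell count {s} < 2 is below the resolution of the doubling model; "
            "developmental divisions set to 0",
            stacklevel=2,
        )
        return 0.0
    if float(s).is_integer():
        k = int(s).bit_length() - 1  # exact floor(log2 s) for integral s
    else:
        k = math.floor(math.log2(s))
        if 2 ** (k + 1) <= s:  # guard float log2 round-down at power boundaries
            k += 1
    return float(2 ** (k + 1) - 2)


def scd_at_age(organ: OrganKinetics, age: float, scale: float = DEFAULT_SCALE) -> float:
    """Scaled cumulative stem-cell divisions of an organ at a given age."""
    if age < 0:
        raise ValidationError("age must be nonnegative")
    if scale <= 0:
        raise ValidationError("scale must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dev = developmental_divisions(organ.s)
    return (dev + organ.s * age * organ.d_yr) / scale


def risk_curve(
    organ: OrganKinetics,
    ages: Sequence[float],
    scale: float = DEFAULT_SCALE,
) -> RiskCurve:
    """Tabulate SCD(age) at the given ages and fit the linear risk curve f1.

    SCD is affine in age, so a degree-1 polynomial-in-age fit is exact:
    slope s*d_yr/scale, intercept developmental term/scale.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValidationError("ages must be nonempty")
    values = np.array([scd_at_age(organ, a, scale) for a in ages])
    series = AgeSeries(ages=ages, values=values, label=f"SCD:{organ.organ}")
    fitted = fit_age_curve(series, basis_families=("poly",), max_degree=1)
    return RiskCurve(organ=organ.organ, scale=scale, curve=fitted)


def risk_curve_from_series(series: AgeSeries, label: str = "", **fit_kwargs) -> RiskCurve:
    """Drop-in alternative when no kinetics are available.

    Some sites lack published stem-cell kinetics; an externally supplied risk
    series (e.g. registry lifetime risk by age) is fitted in place of SCD.
    """
    fitted = fit_age_curve(series, **fit_kwargs)
    return RiskCurve(organ=label or series.label, scale=1.0, curve=fitted)
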