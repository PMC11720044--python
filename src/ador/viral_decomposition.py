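"""Decomposing bimodal incidence curves by viral-infection status.

Liver and cervical cancers show two incidence peaks; the early peak tracks
viral infection (HBV/HCV, HPV 16/18).  Given the age-dependent conditional
probability of infection among patients, fcv(x), the observed rate y(x)
splits exactly into an infection-attributable and an infection-free part:

    y_v(x)  = y(x) * fcv(x)
    y_nv(x) = y(x) * (1 - fcv(x))

fcv is estimated from tumor-cohort metadata by 5-year age bins (sparse bins
imputed from their nearest populated neighbours) and fitted to a continuous
curve on ages 20-90, clipped to [0, 1].  Population background infection
curves are built the same way from cohort serology: HBV positivity requires
both surface antigen and core antibody, HCV requires detectable RNA, HPV
uses the 16/18 positivity flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .age_curves import AgeSeries, FittedCurve, fit_age_curve
from .errors import InsufficientCohortError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "InfectionCurve",
    "DecomposedAdor",
    "conditional_infection_curve",
    "decompose_ador",
    "population_infection_curve",
    "VIRUS_DEFINITIONS",
]

#: marker logic per virus: column(s) that must all be truthy
VIRUS_DEFINITIONS = {
    "HBV": ("hbv_surface_antigen", "hbv_core_antibody"),
    "HCV": ("hcv_rna",),
    "HPV16/18": ("hpv16_18",),
}

DEFAULT_DOMAIN = (20.0, 90.0)


class _InterpCurve:
    """Piecewise-linear probability curve on an age grid (clamped outside)."""

    def __init__(self, ages, values):
        self.ages = np.asarray(ages, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.domain = (float(self.ages[0]), float(self.ages[-1]))

    def __call__(self, ages):
        return np.interp(np.asarray(ages, dtype=float), self.ages, self.values)


@dataclass
class InfectionCurve:
    """Age-dependent infection probability, clipped to [0, 1].

    ``curve`` is usually a :class:`FittedCurve` (the regression route); an
    interpolating curve is used when per-age fractions are taken as given —
    a global polynomial's small tail ripple, multiplied by large old-age
    rates, would otherwise leak mass into the infection component.
    """

    virus: str
    context: str  # 'tumor-conditional' or 'population'
    curve: FittedCurve | _InterpCurve
    sex: str = "both"

    def __call__(self, ages):
        vals = np.clip(self.curve(ages), 0.0, 1.0)
        return vals

    @classmethod
    def from_series(cls, ages, values, virus="virus",
                    context="tumor-conditional", sex="both") -> "InfectionCurve":
        """Build a curve by interpolating known per-age infection fractions."""
        values = np.asarray(values, dtype=float)
        if (values < 0).any() or (values > 1).any():
            raise ValidationError("infection fractions must lie in [0, 1]")
        return cls(virus=virus, context=context,
                   curve=_InterpCurve(ages, values), sex=sex)


@dataclass
class DecomposedAdor:
    """The two additive components of a rate series by infection status."""

    with_infection: AgeSeries
    without_infection: AgeSeries


def _binned_fractions(ages: np.ndarray, flags: np.ndarray,
                      bin_width: float, min_count: int):
    """Per-bin infection fraction and mean age, with sparse-bin imputation."""
    lo = np.floor(ages.min() / bin_width) * bin_width
    hi = np.ceil((ages.max() + 1e-9) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(ages, edges) - 1, 0, len(edges) - 2)

    centers, fracs, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        centers.append(float(ages[mask].mean()))
        fracs.append(float(flags[mask].mean()))
        counts.append(cnt)
    centers = np.asarray(centers)
    fracs = np.asarray(fracs)
    counts = np.asarray(counts)
    if len(centers) < 2:
        raise InsufficientCohortError("need at least 2 nonempty age bins")

    dense = counts >= min_count
    if not dense.any():
        raise InsufficientCohortError("insufficient cohort: every age bin is sparse")
    imputed = fracs.copy()
    dense_idx = np.flatnonzero(dense)
    for i in np.flatnonzero(~dense):
        left = dense_idx[dense_idx < i]
        right = dense_idx[dense_idx > i]
        vals = []
        if left.size:
            vals.append(fracs[left[-1]])
        if right.size:
            vals.append(fracs[right[0]])
        imputed[i] = float(np.mean(vals))  # one-sided at boundaries
    return centers, imputed


def _fit_infection(centers, fracs, virus, context, sex="both",
                   **fit_kwargs) -> InfectionCurve:
    # the curve's domain stays at the observed bin-center range; evaluation
    # on the standard 20-90 reporting window clamps at the margins, which
    # avoids polynomial blow-up left/right of the data
    series = AgeSeries(ages=centers, values=fracs, label=f"{virus} infection ({context})")
    fitted = fit_age_curve(series, **fit_kwargs)
    return InfectionCurve(virus=virus, context=context, curve=fitted, sex=sex)


def conditional_infection_curve(
    samples: pd.DataFrame,
    virus: str = "virus",
    status_column: str = "infected",
    bin_width: float = 5.0,
    min_count: int = 5,
    **fit_kwargs,
) -> InfectionCurve:
    """Estimate fcv(x): infection probability conditional on being a patient.

    ``samples`` needs columns ``age`` and ``status_column`` (boolean/0-1, one
    row per tumor sample).  Fractions are computed per ``bin_width``-year age
    bin; bins with fewer than ``min_count`` samples take the mean of their
    nearest populated neighbours' fractions.
    """
    df = samples.dropna(subset=["age", status_column])
    if df.empty:
        raise InsufficientCohortError("no usable samples")
    centers, fracs = _binned_fractions(
        df["age"].to_numpy(dtype=float),
        df[status_column].to_numpy(dtype=float),
        bin_width, min_count,
    )
    return _fit_infection(centers, fracs, virus, "tumor-conditional", **fit_kwargs)


def decompose_ador(y: AgeSeries, fcv: InfectionCurve) -> DecomposedAdor:
    """Split y(x) into infection-attributable and infection-free components.

    Conservation holds by construction: y_v + y_nv = y at every age.
    """
    f = np.asarray(fcv(y.ages), dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise AssertionError("infection curve produced values outside [0, 1]")
    yv = y.values * f
    ynv = y.values * (1.0 - f)
    return DecomposedAdor(
        with_infection=AgeSeries(y.ages, yv, label=f"{y.label} with {fcv.virus}", sex=y.sex),
        without_infection=AgeSeries(y.ages, ynv, label=f"{y.label} without {fcv.virus}", sex=y.sex),
    )


def population_infection_curve(
    cohort: pd.DataFrame,
    virus: str,
    definitions: dict[str, tuple[str, ...]] = VIRUS_DEFINITIONS,
    sex: str | None = None,
    bin_width: float = 5.0,
    min_count: int = 5,
    **fit_kwargs,
) -> InfectionCurve:
    """Background infection-rate curve from a population serology cohort.

    Infection status per individual follows the marker logic in
    ``definitions`` (all listed columns must be positive).  ``sex`` restricts
    to one sex for stratified curves.
    """
    if virus not in definitions:
        raise ValidationError(f"no marker definition for virus {virus!r}")
    markers = definitions[virus]
    for col in markers:
        if col not in cohort.columns:
            raise ValidationError(f"cohort is missing required marker column {col!r}")
    df = cohort
    if sex is not None:
        df = df[df["sex"] == sex]
        if df.empty:
            raise InsufficientCohortError(f"no individuals of sex {sex!r}")
    status = np.ones(len(df), dtype=bool)
    for col in markers:
        status &= df[col].astype(bool).to_numpy()
    centers, fracs = _binned_fractions(
        df["age"].to_numpy(dtype=float), status.astype(float), bin_width, min_count
    )
    return _fit_infection(centers, fracs, virus, "population",
                          sex=sex or "both", **fit_kwargs)
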