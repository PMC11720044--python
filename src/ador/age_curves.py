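"""Continuous approximation of discrete age-indexed observations.

Cancer registries report occurrence rates at a handful of discrete ages
(typically 20, 30, ..., 80 per 100,000 person-years).  Downstream modelling
needs a continuous rate function y_p(x), so this module fits small polynomial
bases — in age, and in log(age+1) to capture the saturating shapes common in
incidence data — selects the candidate with the best adjusted R², and
characterises the modality (peak ages) of the fitted curve.

Evaluation outside the observed age window is clamped to the boundary value:
low-degree polynomials extrapolate violently, and a spurious mode outside the
data would corrupt modality calls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import UnderdeterminedFitError, ValidationError

__all__ = [
    "AgeSeries",
    "FittedCurve",
    "ModalityReport",
    "fit_age_curve",
    "detect_modes",
]

#: supported basis families, by identifier
BASIS_FAMILIES = ("poly", "logpoly")


def _basis_transform(basis: str, ages: np.ndarray) -> np.ndarray:
    if basis == "poly":
        return ages
    if basis == "logpoly":
        return np.log(ages + 1.0)
    raise ValidationError(f"unknown basis family {basis!r}; expected one of {BASIS_FAMILIES}")


@dataclass(frozen=True)
class AgeSeries:
    """Discrete (age, value) observations, e.g. a registry incidence table."""

    ages: np.ndarray
    values: np.ndarray
    label: str = ""
    sex: str = "both"

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.ndim != 1 or values.shape != ages.shape:
            raise ValidationError("ages and values must be 1-D arrays of equal length")
        if ages.size < 3:
            raise ValidationError("an AgeSeries needs at least 3 points")
        if not np.all(np.diff(ages) > 0):
            raise ValidationError("ages must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValidationError("values must be finite")
        if self.sex not in ("male", "female", "both"):
            raise ValidationError("sex must be 'male', 'female' or 'both'")

    def __len__(self) -> int:
        return self.ages.size


@dataclass
class FittedCurve:
    """A fitted continuous approximation on a bounded age domain.

    ``coefficients`` are ordered highest degree first (``numpy.polyval``
    convention) in the transformed variable of ``basis``.
    """

    basis: str
    coefficients: np.ndarray
    domain: tuple[float, float]
    r2: float
    r2_adjusted: float
    pvalues: np.ndarray
    overall_p: float = float("nan")
    label: str = ""
    #: standard error of prediction of the mean, aligned with coefficients'
    #: design; kept so confidence bands can be drawn without refitting
    _model_result: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        self.pvalues = np.atleast_1d(np.asarray(self.pvalues, dtype=float))
        lo, hi = self.domain
        if not lo < hi:
            raise ValidationError("curve domain must have positive width")

    @property
    def degree(self) -> int:
        return self.coefficients.size - 1

    def __call__(self, ages) -> np.ndarray:
        """Evaluate the curve; ages outside the domain are clamped."""
        ages = np.asarray(ages, dtype=float)
        scalar = ages.ndim == 0
        clipped = np.clip(ages, *self.domain)
        t = _basis_transform(self.basis, np.atleast_1d(clipped))
        out = np.polyval(self.coefficients, t)
        return float(out[0]) if scalar else out

    def confidence_band(self, ages, alpha: float = 0.05):
        """Pointwise (1-alpha) confidence interval of the mean curve.

        Returns (lower, upper) arrays.  Requires the fit to have been produced
        by :func:`fit_age_curve` (the underlying OLS result is retained).
        """
        if self._model_result is None:
            raise ValidationError("confidence bands require a curve produced by fit_age_curve")
        ages = np.atleast_1d(np.clip(np.asarray(ages, dtype=float), *self.domain))
        t = _basis_transform(self.basis, ages)
        X = np.vander(t, N=self.coefficients.size, increasing=False)
        pred = self._model_result.get_prediction(X)
        ci = pred.conf_int(alpha=alpha)
        return ci[:, 0], ci[:, 1]

    def to_dict(self) -> dict:
        return {
            "basis": self.basis,
            "coefficients": list(map(float, self.coefficients)),
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "r2": float(self.r2),
            "r2_adjusted": float(self.r2_adjusted),
            "pvalues": [float(p) for p in self.pvalues],
            "overall_p": float(self.overall_p),
            "label": self.label,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCurve":
        return cls(
            basis=d["basis"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            domain=(d["domain"][0], d["domain"][1]),
            r2=d["r2"],
            r2_adjusted=d["r2_adjusted"],
            pvalues=np.asarray(d["pvalues"], dtype=float),
            overall_p=d.get("overall_p", float("nan")),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class ModalityReport:
    """Peak structure of a fitted curve."""

    n_modes: int
    peak_ages: tuple[float, ...]
    classification: str

    def __post_init__(self):
        if self.n_modes != len(self.peak_ages):
            raise ValidationError("n_modes must equal the number of peak ages")


def _fit_one(t: np.ndarray, y: np.ndarray, degree: int):
    """OLS polynomial fit of y on t; returns (coeffs hi->lo, result, r2, r2adj)."""
    X = np.vander(t, N=degree + 1, increasing=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, X).fit()
    ss_res = float(np.sum(res.resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, k = y.size, degree + 1
    if ss_tot <= 1e-300:
        # constant data: every exact fit is perfect; define r2 accordingly so
        # the adjusted-R2 tie-break can fall through to fewer coefficients
        r2 = 1.0 if ss_res <= 1e-12 * max(1.0, abs(y[0])) else 0.0
        r2_adj = r2
    else:
        r2 = 1.0 - ss_res / ss_tot
        if n - k > 0:
            r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
        else:
            r2_adj = -np.inf
    return res.params, res, r2, r2_adj


def fit_age_curve(
    series: AgeSeries,
    basis_families: Sequence[str] = BASIS_FAMILIES,
    min_degree: int = 0,
    max_degree: int = 5,
) -> FittedCurve:
    """Fit a continuous curve to an age series by scanning basis candidates.

    Scans polynomial degrees ``min_degree..max_degree`` in each basis family
    and returns the candidate maximising adjusted R²; ties are broken toward
    fewer coefficients, then by family order.  Degree 0 (intercept only) is
    included so constant data resolve to a constant curve.

    Raises
    ------
    UnderdeterminedFitError
        if every scanned degree needs more coefficients than there are points.
    """
    if isinstance(basis_families, str):
        basis_families = (basis_families,)
    for b in basis_families:
        if b not in BASIS_FAMILIES:
            raise ValidationError(f"unknown basis family {b!r}")
    if max_degree < min_degree or min_degree < 0:
        raise ValidationError("need 0 <= min_degree <= max_degree")

    y = series.values
    n = y.size
    best = None  # (r2_adj, n_coef, family_rank, curve fields)
    any_fit = False
    for rank, basis in enumerate(basis_families):
        t = _basis_transform(basis, series.ages)
        for degree in range(min_degree, max_degree + 1):
            if degree + 1 > n:
                continue
            any_fit = True
            coefs, res, r2, r2_adj = _fit_one(t, y, degree)
            key = (-r2_adj, degree + 1, rank)
            if best is None or key < best[0]:
                best = (key, basis, coefs, res, r2, r2_adj)
    if not any_fit:
        raise UnderdeterminedFitError(
            f"underdetermined fit: {n} points cannot support degree >= {min_degree}"
        )
    _, basis, coefs, res, r2, r2_adj = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # perfect fits: mse_resid == 0
        overall_p = float(res.f_pvalue) if res.df_model > 0 else float("nan")
        pvalues = np.asarray(res.pvalues, dtype=float)
    return FittedCurve(
        basis=basis,
        coefficients=np.asarray(coefs, dtype=float),
        domain=(float(series.ages[0]), float(series.ages[-1])),
        r2=float(np.clip(r2, 0.0, 1.0)),
        r2_adjusted=float(r2_adj),
        pvalues=pvalues,
        overall_p=overall_p,
        label=series.label,
        _model_result=res,
    )


def detect_modes(
    curve: Callable[[np.ndarray], np.ndarray],
    grid_step: float = 1.0,
    min_separation: float = 5.0,
    min_prominence: float = 0.05,
    domain: tuple[float, float] | None = None,
) -> ModalityReport:
    """Locate the modes (local maxima) of a curve on a regular age grid.

    ``curve`` is typically a :class:`FittedCurve`; an :class:`AgeSeries` is
    evaluated by linear interpolation, and any callable works when
    ``domain`` is given.  Maxima closer than ``min_separation`` are merged
    (the higher one is kept), and maxima whose topographic prominence is
    below ``min_prominence`` times the curve's value range are discarded —
    low-degree polynomial fits ripple slightly near the domain edges, and a
    sub-percent wiggle is not an incidence mode.  Boundary maxima count: a
    rate still rising at the oldest observed age is a right-boundary mode.
    """
    from scipy.signal import find_peaks

    if isinstance(curve, AgeSeries):
        series = curve
        curve = lambda a: np.interp(np.asarray(a, float), series.ages, series.values)
        if domain is None:
            domain = (series.ages[0], series.ages[-1])
    if domain is None:
        domain = getattr(curve, "domain", None)
        if domain is None:
            raise ValidationError("domain must be given for a bare callable")
    lo, hi = float(domain[0]), float(domain[1])
    if not lo < hi:
        raise ValidationError("empty curve domain")
    if not 0 < grid_step < hi - lo:
        raise ValidationError("grid_step must be positive and smaller than the domain width")

    n = int(np.floor((hi - lo) / grid_step)) + 1
    grid = lo + grid_step * np.arange(n)
    if grid[-1] < hi - 1e-9:
        grid = np.append(grid, hi)
    vals = np.asarray(curve(grid), dtype=float)

    vrange = float(vals.max() - vals.min())
    if vrange <= 0:
        # constant curve: a single plateau mode at the domain midpoint
        return ModalityReport(n_modes=1, peak_ages=((lo + hi) / 2.0,),
                              classification="unimodal")

    # pad below the minimum so boundary maxima are real peaks with full prominence
    pad = vals.min() - vrange
    padded = np.concatenate([[pad], vals, [pad]])
    idx, props = find_peaks(padded, prominence=min_prominence * vrange)
    peaks = [(float(grid[i - 1]), float(vals[i - 1])) for i in idx]

    # merge peaks closer than min_separation, keeping the higher
    peaks.sort(key=lambda p: -p[1])
    kept: list[tuple[float, float]] = []
    for age, val in peaks:
        if all(abs(age - a) >= min_separation for a, _ in kept):
            kept.append((age, val))
    kept.sort(key=lambda p: p[0])

    n_modes = len(kept)
    classification = {1: "unimodal", 2: "bimodal"}.get(n_modes, "other")
    return ModalityReport(
        n_modes=n_modes,
        peak_ages=tuple(a for a, _ in kept),
        classification=classification,
    )
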