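"""All-subsets regression of ADOR distributions on risk and support curves.

An occurrence-rate series y(x) is regressed on a candidate design built from
the organ's risk curve f1(x), the support curves of its predicted growth
signals, optional extra curves (e.g. population infection rates), and the
risk x signal / risk x extra interaction products.  Every subset of the
candidate terms up to ``max_terms`` is fitted by OLS with intercept; subsets
in which any non-intercept coefficient fails significance at ``alpha`` are
discarded; among the admissible subsets the one with the highest adjusted R²
wins, with deterministic tie-breaks (fewer terms, then lexicographic ids).

Exhaustive enumeration is deliberate: the candidate spaces in this problem
are small (a risk curve plus one to three signals), and the optimality
certificate is exact rather than greedy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm

from .age_curves import AgeSeries
from .errors import NoSignificantModelError, ValidationError

__all__ = ["Term", "TermSet", "RegressionModel", "build_term_set", "all_subsets_fit"]


@dataclass(frozen=True)
class Term:
    """One candidate regression term: an intercept, a curve, or a product."""

    term_id: str
    kind: str  # 'intercept' | 'main' | 'interaction'
    factors: tuple[str, ...]


@dataclass
class TermSet:
    """Candidate terms with their values tabulated at the observation ages."""

    terms: list[Term]
    evaluations: np.ndarray  # shape (n_ages, n_terms), column order == terms
    ages: np.ndarray

    def __post_init__(self):
        if self.terms[0].kind != "intercept":
            raise ValidationError("first term must be the intercept")
        if self.evaluations.shape != (self.ages.size, len(self.terms)):
            raise ValidationError("evaluations shape must be (n_ages, n_terms)")

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    def columns(self, ids: Sequence[str]) -> np.ndarray:
        index = {t.term_id: j for j, t in enumerate(self.terms)}
        return self.evaluations[:, [index[i] for i in ids]]


@dataclass
class RegressionModel:
    """A selected ADOR model: terms, coefficients, diagnostics."""

    selected_terms: list[str]  # non-intercept term ids, design order
    coefficients: np.ndarray  # intercept last, matching published model style
    pvalues: np.ndarray
    r2: float
    r2_adjusted: float
    overall_p: float
    n_subsets_enumerated: int = 0

    def predict(self, terms: TermSet) -> np.ndarray:
        X = terms.columns(self.selected_terms)
        return X @ self.coefficients[:-1] + self.coefficients[-1]

    def to_dict(self) -> dict:
        return {
            "selected_terms": list(self.selected_terms),
            "coefficients": [float(c) for c in self.coefficients],
            "pvalues": [float(p) for p in self.pvalues],
            "r2": float(self.r2),
            "r2_adjusted": float(self.r2_adjusted),
            "overall_p": float(self.overall_p),
        }


def build_term_set(
    risk: Callable,
    signals: Sequence[tuple[str, Callable]],
    ages: Sequence[float],
    extras: Sequence[tuple[str, Callable]] = (),
    risk_id: str = "risk",
) -> TermSet:
    """Assemble the candidate design: mains plus risk-interaction products.

    ``signals`` and ``extras`` are (id, curve) pairs; any callable evaluable
    at the ages works (FittedCurve, RiskCurve, InfectionCurve...).  Candidate
    terms are the intercept, each curve as a main effect, and risk x signal /
    risk x extra products — the smallest space containing every published
    model shape.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValidationError("ages must be nonempty")
    ids = [risk_id] + [sid for sid, _ in signals] + [eid for eid, _ in extras]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate curve ids in term set")

    risk_vals = np.asarray(risk(ages), dtype=float)
    terms = [Term("1", "intercept", ())]
    cols = [np.ones_like(ages)]
    terms.append(Term(risk_id, "main", (risk_id,)))
    cols.append(risk_vals)
    for sid, curve in list(signals) + list(extras):
        terms.append(Term(sid, "main", (sid,)))
        cols.append(np.asarray(curve(ages), dtype=float))
    for sid, curve in list(signals) + list(extras):
        tid = f"{risk_id}*{sid}"
        terms.append(Term(tid, "interaction", (risk_id, sid)))
        cols.append(risk_vals * np.asarray(curve(ages), dtype=float))
    return TermSet(terms=terms, evaluations=np.column_stack(cols), ages=ages)


def _ols(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.OLS(y, X).fit()


def all_subsets_fit(
    ador: AgeSeries,
    terms: TermSet,
    max_terms: int = 5,
    alpha: float = 0.05,
) -> RegressionModel:
    """Exhaustive best-subset OLS under the all-coefficients-significant rule.

    Enumerates every subset of non-intercept terms of size <= ``max_terms``
    (the intercept is always included).  A subset is admissible when every
    non-intercept coefficient has p < ``alpha``; the admissible subset with
    the highest adjusted R² is returned.  Ties break to fewer terms, then to
    lexicographically smaller term-id tuples, making the result independent
    of observation order and enumeration order.

    Raises
    ------
    NoSignificantModelError
        when no nonempty subset is admissible; the best inadmissible fit is
        attached as ``diagnostics``.
    """
    if max_terms > 8:
        raise ValidationError("max_terms > 8 exceeds the exhaustive enumeration bound")
    candidates = [t.term_id for t in terms.terms if t.kind != "intercept"]
    y = ador.values
    if y.size <= max_terms + 1:
        raise ValidationError("need more observations than max_terms + 1")

    best = None  # (sort key, model fields)
    best_inadmissible = None  # (r2_adj, model fields) regardless of significance
    n_enumerated = 0
    for size in range(0, min(max_terms, len(candidates)) + 1):
        for subset in itertools.combinations(candidates, size):
            n_enumerated += 1
            if size == 0:
                continue  # intercept-only is never reported as a model
            X = np.column_stack([terms.columns(list(subset)), np.ones(y.size)])
            res = _ols(y, X)
            r2_adj = float(res.rsquared_adj)
            fields = (list(subset), np.asarray(res.params), np.asarray(res.pvalues),
                      float(res.rsquared), r2_adj, float(res.f_pvalue))
            if best_inadmissible is None or r2_adj > best_inadmissible[0]:
                best_inadmissible = (r2_adj, fields)
            coef_p = res.pvalues[:-1]  # non-intercept coefficients
            if np.any(~np.isfinite(coef_p)) or np.any(coef_p >= alpha):
                continue
            key = (-round(r2_adj, 12), size, tuple(subset))
            if best is None or key < best[0]:
                best = (key, fields)

    if best is None:
        diag = None
        if best_inadmissible is not None:
            diag = _to_model(best_inadmissible[1], n_enumerated)
        raise NoSignificantModelError(
            f"no significant model at alpha={alpha} among {n_enumerated} subsets",
            diagnostics=diag,
        )
    return _to_model(best[1], n_enumerated)


def _to_model(fields, n_enumerated: int) -> RegressionModel:
    subset, params, pvals, r2, r2_adj, fp = fields
    return RegressionModel(
        selected_terms=subset,
        coefficients=params,
        pvalues=pvals,
        r2=r2,
        r2_adjusted=r2_adj,
        overall_p=fp,
        n_subsets_enumerated=n_enumerated,
    )
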