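"""Gender disparity in occurrence rates and its iron/hormone correlates.

Most cancer types occur more often in males.  The disparity at each age is
quantified as the log2 rate ratio

    fd(age) = log2( rate_male(age) / rate_female(age) )

and regressed, by forward selection, on the per-age log2 fold changes of
iron-handling gene expression between the sexes in normal tissue,

    FC_j(age) = log2( (median male expr_j + 1) / (median female expr_j + 1) ),

or — for the female-dominant thyroid case — on a circulating-hormone fold
change series.  Serum iron analytes (iron, ferritin, transferrin saturation,
hemoglobin) are compared between sexes per age bin with the Wilcoxon
rank-sum test, and the ferritin-cancer association is assessed with a group
label permutation test: the p-value is the fraction of random label
reassignments whose cancer-group mean strictly exceeds the observed one
(no +1 smoothing, exactly as the estimator is defined; an optional smoothed
variant is provided for users who need a never-zero p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .age_curves import AgeSeries
from .cluster_attribution import forward_select
from .errors import ValidationError
from .signal_discovery import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "GenderRatioSeries",
    "IronGeneFC",
    "PermutationResult",
    "gender_ratio_series",
    "iron_gene_fc",
    "fit_ratio_model",
    "ferritin_permutation_test",
    "serum_gender_compare",
]


@dataclass
class GenderRatioSeries:
    """log2 male/female rate ratio per age (ages with a zero rate excluded)."""

    ages: np.ndarray
    fd: np.ndarray
    excluded_ages: tuple[float, ...] = ()

    def __len__(self) -> int:
        return self.ages.size


@dataclass
class IronGeneFC:
    """Per-gene, per-age-bin male/female expression fold change (log2)."""

    fc: pd.DataFrame  # rows = bin center ages, columns = genes
    dropped_bins: tuple[float, ...] = ()

    @property
    def ages(self) -> np.ndarray:
        return self.fc.index.to_numpy(dtype=float)

    @property
    def genes(self) -> list[str]:
        return list(self.fc.columns)


def gender_ratio_series(male: AgeSeries, female: AgeSeries) -> GenderRatioSeries:
    """fd(age) = log2(male rate / female rate) on the shared age grid."""
    shared = np.intersect1d(male.ages, female.ages)
    if shared.size == 0:
        raise ValidationError("male and female series share no ages")
    mv = male.values[np.isin(male.ages, shared)]
    fv = female.values[np.isin(female.ages, shared)]
    ok = (mv > 0) & (fv > 0)
    excluded = tuple(float(a) for a in shared[~ok])
    if excluded:
        logger.warning("ages with a zero rate excluded from fd: %s", excluded)
    if not ok.any():
        raise ValidationError("no age has positive rates in both sexes")
    return GenderRatioSeries(ages=shared[ok], fd=np.log2(mv[ok] / fv[ok]),
                             excluded_ages=excluded)


def iron_gene_fc(
    study: ExpressionStudy,
    iron_genes: Sequence[str],
    age_bins: Sequence[float],
) -> IronGeneFC:
    """Median-based sex fold change of each gene per age bin (pseudocount 1).

    ``age_bins`` are bin edges; a bin missing either sex is dropped with a
    warning.  The pseudocount keeps the fold change finite even when both
    medians are zero.
    """
    iron_genes = [g for g in iron_genes if g in study.tpm.index]
    if not iron_genes:
        raise ValidationError("no iron genes present in the study")
    edges = np.asarray(age_bins, dtype=float)
    meta = study.sample_meta
    rows, centers, dropped = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (meta["age"] >= lo) & (meta["age"] < hi)
        males = meta.index[in_bin & (meta["sex"] == "male")]
        females = meta.index[in_bin & (meta["sex"] == "female")]
        center = (lo + hi) / 2.0
        if len(males) == 0 or len(females) == 0:
            if in_bin.any():
                dropped.append(float(center))
                logger.warning("age bin [%g, %g) has one sex only; dropped", lo, hi)
            continue
        med_m = study.tpm.loc[iron_genes, males].median(axis=1)
        med_f = study.tpm.loc[iron_genes, females].median(axis=1)
        rows.append(np.log2((med_m + 1.0) / (med_f + 1.0)))
        centers.append(float(center))
    if not rows:
        raise ValidationError("no age bin contains both sexes")
    fc = pd.DataFrame(rows, index=centers)
    fc.columns = iron_genes
    return IronGeneFC(fc=fc, dropped_bins=tuple(dropped))


def fit_ratio_model(
    fd: GenderRatioSeries,
    predictors: IronGeneFC | pd.DataFrame,
    alpha: float = 0.05,
):
    """Forward-selection regression of the disparity series on FC predictors.

    ``predictors`` may be an :class:`IronGeneFC` or any DataFrame indexed by
    age (a single hormone FC column works for the single-predictor variant).
    Returns the AttributionResult-style outcome of :func:`forward_select`
    wrapped with coefficients and diagnostics; an intercept-only outcome has
    ``selected_predictors == []``.
    """
    table = predictors.fc if isinstance(predictors, IronGeneFC) else predictors
    table = table.loc[[a for a in fd.ages if a in table.index]]
    if len(table) != fd.ages.size:
        raise ValidationError("predictors must be defined at every fd age")
    if len(table) < 3:
        raise ValidationError("need at least 3 ages to fit the ratio model")
    from .cluster_attribution import AttributionResult, lmg_shares

    y = fd.fd
    selected, res, dropped = forward_select(y, table, alpha=alpha)
    if not selected or res is None:
        return AttributionResult(
            response="fd", selected_predictors=[],
            coefficients=np.array([float(np.mean(y))]), pvalues=np.array([np.nan]),
            r2=0.0, r2_adjusted=0.0, lmg_shares={}, dropped_collinear=dropped,
        )
    return AttributionResult(
        response="fd",
        selected_predictors=selected,
        coefficients=np.asarray(res.params),
        pvalues=np.asarray(res.pvalues),
        r2=float(res.rsquared),
        r2_adjusted=float(res.rsquared_adj),
        lmg_shares=lmg_shares(y, table[selected]),
        dropped_collinear=dropped,
    )


@dataclass
class PermutationResult:
    observed_mean: float
    n_iterations: int
    p_value: float
    seed: int
    n_cancer: int
    n_control: int
    n_dropped: int = 0


def ferritin_permutation_test(
    values: Sequence[float],
    labels: Sequence[str],
    iterations: int = 100_000,
    seed: int = 0,
    smoothed: bool = False,
    cancer_label: str = "cancer",
) -> PermutationResult:
    """Group-label permutation test of an analyte's cancer association.

    Labels are reassigned uniformly at random (a permutation, preserving the
    group sizes n and m); each iteration scores 1 iff the permuted
    cancer-group mean *strictly* exceeds the observed cancer-group mean.
    p = count / iterations as the estimator is defined; ``smoothed=True``
    reports (count + 1) / (iterations + 1) instead.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%d rows with missing analyte values dropped", n_dropped)
    values, labels = values[keep], labels[keep]
    is_cancer = labels == cancer_label
    n, m = int(is_cancer.sum()), int((~is_cancer).sum())
    if n < 1 or m < 1:
        raise ValidationError("need at least one cancer and one control sample")

    observed = float(values[is_cancer].mean())
    rng = np.random.default_rng(seed)
    total = n + m
    count = 0
    chunk = max(1, min(iterations, int(2e7 // max(total, 1))))
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        # vectorised permutation draw: rank of random keys picks n indices
        keys = rng.random((b, total))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        means = values[idx].mean(axis=1)
        count += int(np.sum(means > observed))
        done += b
    p = (count + 1) / (iterations + 1) if smoothed else count / iterations
    return PermutationResult(
        observed_mean=observed, n_iterations=iterations, p_value=float(p),
        seed=seed, n_cancer=n, n_control=m, n_dropped=n_dropped,
    )


def _stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


def serum_gender_compare(
    cohort: pd.DataFrame,
    analyte: str,
    age_bins: Sequence[float],
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of an analyte by sex per age bin.

    Returns a frame with bin bounds, per-sex n, the p-value and a significance
    star code; single-sex bins are skipped.
    """
    if analyte not in cohort.columns:
        raise ValidationError(f"cohort has no column {analyte!r}")
    edges = np.asarray(age_bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = cohort[(cohort["age"] >= lo) & (cohort["age"] < hi)].dropna(subset=[analyte])
        males = sub.loc[sub["sex"] == "male", analyte].to_numpy()
        females = sub.loc[sub["sex"] == "female", analyte].to_numpy()
        if males.size == 0 or females.size == 0:
            continue
        if np.array_equal(np.sort(males), np.sort(females)):
            p = 1.0  # identical samples: no evidence of a shift
        else:
            p = float(stats.mannwhitneyu(males, females, alternative="two-sided").pvalue)
        rows.append({
            "age_lo": lo, "age_hi": hi, "n_male": males.size, "n_female": females.size,
            "p_value": p, "stars": _stars(p),
            "median_male": float(np.median(males)), "median_female": float(np.median(females)),
        })
    return pd.DataFrame(rows)
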