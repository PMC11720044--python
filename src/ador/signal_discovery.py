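"""Discovery of circulating growth signals driving a cancer's cell-cycle program.

The pipeline has three stages:

1. *Core cell-cycle genes.*  Starting from a curated cell-cycle gene list, keep
   only genes strongly co-expressed (PCC > 0.3, BH-FDR < 0.05 on log2(TPM+1)
   profiles) with at least N = 10 other retained genes, iterating the degree
   filter to a fixpoint, then drop the bottom third by co-expression degree.

2. *Candidate driver signals.*  A bloodborne ligand is a candidate driver of
   the cell-cycle program if at least one of its receptors is (a) expressed
   (mean TPM > 5 across tumor samples), (b) >= 1.5-fold upregulated in tumor
   vs. matched control (mean TPM, pseudocount 1), and (c) co-expressed with at
   least 10% of the core cell-cycle genes.

3. *Signal-availability curves.*  The circulating level of a signal at a given
   age is the weighted sum over producing organs, sum_x w_x * L_x(g, age),
   with w = 1.0 for a major producing organ and 0.5 for a minor one.  Brain
   sources other than the hypothalamus are excluded (the blood-brain barrier
   keeps their product out of circulation).  The summed profile is fitted to a
   continuous curve and gated at R² > 0.6 with p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .age_curves import AgeSeries, FittedCurve, fit_age_curve
from .errors import (
    MissingControlCohortError,
    NoAdmissibleSourceError,
    NoCoreSetError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "CoexpressionGraph",
    "CoreGeneSet",
    "CandidateSignal",
    "SignalSource",
    "SignalCurve",
    "coexpression_graph",
    "filter_core_cycle_genes",
    "predict_driver_signals",
    "signal_level_curve",
]


@dataclass
class ExpressionStudy:
    """Genes x samples expression with per-sample metadata.

    ``tpm`` (and optionally ``counts``) are DataFrames indexed by gene id with
    sample ids as columns; ``sample_meta`` is indexed by sample id and carries
    at least ``age``, ``sex`` and ``condition`` ('tumor'/'control'), plus any
    viral-status flag columns.
    """

    tpm: pd.DataFrame
    sample_meta: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.tpm.columns.equals(pd.Index(self.sample_meta.index)):
            if set(self.tpm.columns) != set(self.sample_meta.index):
                raise ValidationError("tpm columns and sample_meta index must match")
            self.sample_meta = self.sample_meta.loc[self.tpm.columns]
        if self.counts is not None and self.counts.shape != self.tpm.shape:
            raise ValidationError("counts and tpm must have identical shape")
        if (self.tpm.values < 0).any():
            raise ValidationError("TPM values must be nonnegative")
        if "age" in self.sample_meta:
            ages = self.sample_meta["age"].dropna()
            if ((ages < 0) | (ages > 120)).any():
                raise ValidationError("sample ages must lie in [0, 120]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    def samples_where(self, condition: str | None = None) -> list[str]:
        if condition is None:
            return self.sample_ids
        mask = self.sample_meta["condition"] == condition
        return list(self.sample_meta.index[mask])

    def log2_tpm(self, genes: Sequence[str] | None = None,
                 samples: Sequence[str] | None = None) -> pd.DataFrame:
        sub = self.tpm
        if genes is not None:
            missing = set(genes) - set(sub.index)
            if missing:
                raise ValidationError(f"genes not in study: {sorted(missing)[:5]}...")
            sub = sub.loc[list(genes)]
        if samples is not None:
            sub = sub[list(samples)]
        return np.log2(sub + 1.0)


@dataclass
class CoexpressionGraph:
    """Co-expression edges: pairs with PCC above threshold at controlled FDR."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: gene_i, gene_j, pcc, fdr
    pcc_threshold: float
    fdr_threshold: float
    _adj: dict = field(default=None, repr=False)

    def __post_init__(self):
        if self._adj is None:
            adj: dict[str, set[str]] = {g: set() for g in self.nodes}
            for gi, gj in zip(self.edges["gene_i"], self.edges["gene_j"]):
                adj[gi].add(gj)
                adj[gj].add(gi)
            self._adj = adj

    def neighbors(self, gene: str) -> set[str]:
        return self._adj[gene]

    def degree(self, gene: str) -> int:
        return len(self._adj[gene])

    def subgraph_degrees(self, genes: Iterable[str]) -> dict[str, int]:
        keep = set(genes)
        return {g: len(self._adj[g] & keep) for g in keep}


def _pearson_edges(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairwise PCC and two-sided p-values of the rows of X."""
    n = X.shape[1]
    sd = X.std(axis=1)
    const = sd <= 1e-12
    if const.any():
        logger.info("%d constant profiles: correlations undefined, left isolated",
                    int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    iu, ju = np.triu_indices(X.shape[0], k=1)
    rv = r[iu, ju]
    rv[const[iu] | const[ju]] = np.nan
    rv = np.clip(rv, -0.9999999999, 0.9999999999)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.column_stack([iu, ju]), rv, p


def coexpression_graph(
    study: ExpressionStudy,
    genes: Sequence[str],
    pcc_threshold: float = 0.3,
    fdr_threshold: float = 0.05,
    condition: str | None = None,
) -> CoexpressionGraph:
    """Build the co-expression graph over ``genes`` on log2(TPM+1) profiles.

    An edge requires PCC strictly above ``pcc_threshold`` (one-sided: strong
    anti-correlation yields no edge) and BH-adjusted p below ``fdr_threshold``;
    the BH family is all pairs tested in this invocation.
    """
    genes = list(dict.fromkeys(genes))
    samples = study.samples_where(condition)
    if len(samples) < 3:
        raise ValidationError("coexpression needs at least 3 samples")
    X = study.log2_tpm(genes, samples).values
    pairs, rv, p = _pearson_edges(X)
    ok = np.isfinite(rv)
    fdr = np.full_like(p, np.nan)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    keep = ok & (rv > pcc_threshold) & (fdr < fdr_threshold)
    edges = pd.DataFrame({
        "gene_i": [genes[i] for i in pairs[keep, 0]],
        "gene_j": [genes[j] for j in pairs[keep, 1]],
        "pcc": rv[keep],
        "fdr": fdr[keep],
    })
    return CoexpressionGraph(nodes=genes, edges=edges,
                             pcc_threshold=pcc_threshold, fdr_threshold=fdr_threshold)


@dataclass
class CoreGeneSet:
    """Cell-cycle genes surviving the iterative co-expression degree filter."""

    genes: list[str]
    degree: dict[str, int]  # within-set degree at the pre-ranking fixpoint
    provenance: dict

    def __len__(self) -> int:
        return len(self.genes)


def filter_core_cycle_genes(
    study: ExpressionStudy,
    seed_genes: Sequence[str],
    N: int = 10,
    drop_fraction: float = 1.0 / 3.0,
    pcc_threshold: float = 0.3,
    fdr_threshold: float = 0.05,
    condition: str | None = None,
    graph: CoexpressionGraph | None = None,
) -> CoreGeneSet:
    """Reduce a curated cell-cycle list to its co-expressed core.

    Round by round, all genes whose within-set co-expression degree is below
    ``N`` are removed simultaneously, until no gene changes (fixpoint).  The
    survivors are then ranked by degree and the lowest floor(drop_fraction * n)
    are dropped, ties resolved by lexicographic gene id.
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    seed_genes = list(dict.fromkeys(seed_genes))
    if graph is None:
        graph = coexpression_graph(study, seed_genes, pcc_threshold, fdr_threshold, condition)

    current = set(seed_genes)
    rounds = 0
    removed_per_round: list[int] = []
    while True:
        deg = graph.subgraph_degrees(current)
        low = {g for g, d in deg.items() if d < N}
        if not low:
            break
        current -= low
        rounds += 1
        removed_per_round.append(len(low))
        if not current:
            raise NoCoreSetError(
                "no core set: every gene fell below the degree threshold",
                diagnostics={"rounds": rounds, "removed_per_round": removed_per_round, "N": N},
            )

    fix_degrees = graph.subgraph_degrees(current)
    n_drop = int(np.floor(drop_fraction * len(current)))
    ranked = sorted(fix_degrees.items(), key=lambda kv: (kv[1], kv[0]))
    dropped = {g for g, _ in ranked[:n_drop]}
    kept = sorted(current - dropped)
    if not kept:
        raise NoCoreSetError("no core set: bottom-third removal emptied the set",
                             diagnostics={"rounds": rounds, "N": N})
    return CoreGeneSet(
        genes=kept,
        degree={g: fix_degrees[g] for g in kept},
        provenance={
            "N": N,
            "drop_fraction": drop_fraction,
            "pcc_threshold": pcc_threshold,
            "fdr_threshold": fdr_threshold,
            "fixpoint_rounds": rounds,
            "removed_per_round": removed_per_round,
            "bottom_dropped": sorted(dropped),
            "fixpoint_size": len(current),
        },
    )


@dataclass(frozen=True)
class CandidateSignal:
    """A bloodborne ligand whose receptor passes all three driver gates."""

    ligand: str
    receptors: tuple[str, ...]
    receptor_mean_tpm: float
    receptor_fold_change: float
    core_coexpression_fraction: float
    bloodborne: bool = True


def predict_driver_signals(
    core: CoreGeneSet,
    study: ExpressionStudy,
    annotations: pd.DataFrame,
    tpm_min: float = 5.0,
    fc_min: float = 1.5,
    core_fraction_min: float = 0.10,
    pcc_threshold: float = 0.3,
    fdr_threshold: float = 0.05,
) -> list[CandidateSignal]:
    """Predict candidate driving signals for a cancer's cell-cycle program.

    ``annotations`` needs columns ligand, receptor, bloodborne.  A ligand is
    retained iff it is bloodborne and at least one of its receptors passes the
    expression, upregulation and core-co-expression gates (module docstring).
    Receptor-core co-expression shares one BH family per receptor invocation.
    """
    if annotations.empty:
        raise ValidationError("annotations table is empty")
    tumor = study.samples_where("tumor")
    control = study.samples_where("control")
    if not control:
        raise MissingControlCohortError("missing control cohort: no control samples in study")
    if not tumor:
        raise ValidationError("study contains no tumor samples")

    pairs = annotations[["ligand", "receptor", "bloodborne"]].drop_duplicates()
    out: list[CandidateSignal] = []
    for ligand, grp in pairs.groupby("ligand", sort=True):
        if not grp["bloodborne"].astype(bool).all():
            continue
        passing: list[tuple[str, float, float, float]] = []
        for receptor in sorted(grp["receptor"].unique()):
            if receptor not in study.tpm.index:
                continue
            mean_t = float(study.tpm.loc[receptor, tumor].mean())
            if not mean_t > tpm_min:
                continue
            mean_c = float(study.tpm.loc[receptor, control].mean())
            fc = (mean_t + 1.0) / (mean_c + 1.0)
            if fc < fc_min:
                continue
            g = coexpression_graph(
                study, list(core.genes) + [receptor],
                pcc_threshold, fdr_threshold, condition="tumor",
            )
            frac = len(g.neighbors(receptor) & set(core.genes)) / len(core.genes)
            if frac < core_fraction_min:
                continue
            passing.append((receptor, mean_t, fc, frac))
        if passing:
            best = max(passing, key=lambda p: p[3])
            out.append(CandidateSignal(
                ligand=ligand,
                receptors=tuple(r for r, *_ in passing),
                receptor_mean_tpm=best[1],
                receptor_fold_change=best[2],
                core_coexpression_fraction=best[3],
            ))
    return out


@dataclass(frozen=True)
class SignalSource:
    """One organ producing a signal, with its age profile and contribution role."""

    organ: str
    role: str  # 'major' or 'minor'
    expression_by_age: AgeSeries
    is_brain: bool = False
    is_hypothalamus: bool = False

    def __post_init__(self):
        if self.role not in ("major", "minor"):
            raise ValidationError("role must be 'major' or 'minor'")

    @property
    def weight(self) -> float:
        return 1.0 if self.role == "major" else 0.5

    @property
    def admissible(self) -> bool:
        # blood-brain barrier: brain organs do not contribute to circulation,
        # except the hypothalamus (hypophyseal portal access)
        return (not self.is_brain) or self.is_hypothalamus


@dataclass
class SignalCurve:
    """Fitted age-availability curve of a signal, with its quality gate."""

    signal: str
    curve: FittedCurve
    gate_passed: bool
    r2: float
    p_value: float

    def __call__(self, ages):
        return self.curve(ages)


def signal_level_curve(
    signal: str,
    sources: Sequence[SignalSource] = (),
    nonprotein_series: AgeSeries | None = None,
    r2_gate: float = 0.6,
    p_gate: float = 0.05,
    **fit_kwargs,
) -> SignalCurve:
    """Fit the age-dependent circulating availability curve of a signal.

    The production level at each age is sum_x w_x * L_x(signal, age) over
    admissible sources.  For non-protein hormones (e.g. estradiol) a measured
    serum series replaces the production sum.
    """
    if nonprotein_series is not None:
        series = AgeSeries(nonprotein_series.ages, nonprotein_series.values,
                           label=signal, sex=nonprotein_series.sex)
    else:
        admissible = [s for s in sources if s.admissible]
        if not admissible:
            raise NoAdmissibleSourceError(
                f"no admissible source for {signal}: all producing organs are "
                "brain-resident (non-hypothalamus)"
            )
        ages = admissible[0].expression_by_age.ages
        for s in admissible[1:]:
            if not np.array_equal(s.expression_by_age.ages, ages):
                raise ValidationError("all sources must share one age grid")
        total = np.zeros_like(ages, dtype=float)
        for s in admissible:
            total += s.weight * s.expression_by_age.values
        series = AgeSeries(ages=ages, values=total, label=signal)
    fitted = fit_age_curve(series, **fit_kwargs)
    r2 = fitted.r2
    p = fitted.overall_p
    gate = bool(r2 > r2_gate and np.isfinite(p) and p < p_gate)
    return SignalCurve(signal=signal, curve=fitted, gate_passed=gate, r2=r2, p_value=p)
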