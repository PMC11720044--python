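"""Co-expressed cell-cycle clusters and what drives their activity.

Core cell-cycle genes are grouped by consensus clustering: hierarchical
clustering (distance 1 - PCC on log2(TPM+1) profiles, average linkage) is run
100 times, each on a random 80% subsample of the genes; the consensus matrix
records how often each gene pair co-clusters among the iterations in which
both were sampled.  The number of clusters k is chosen by the largest
relative increase in the area under the consensus CDF; clusters with fewer
than 20 genes are dropped.

Each retained cluster is summarised by the first principal component (PC1)
of its member genes, sign-oriented so that most member genes correlate
positively with the reported activity.  Cluster activity is then attributed
to receptor expression, a de novo deoxyribonucleotide-synthesis score, and
the activities of the other clusters via forward-selection OLS, with each
selected predictor's relative importance quantified by the LMG method
(its sequential R² contribution averaged over all predictor orderings) and
generalisation checked by 10-fold cross-validated random-forest regression.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .errors import DegenerateClusterError, ValidationError
from .signal_discovery import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusClustering",
    "ClusterActivity",
    "AttributionResult",
    "consensus_cluster",
    "cluster_activity",
    "attribute_activity",
    "cv_validate",
    "nucleotide_synthesis_score",
    "load_dntp_synthesis_genes",
    "lmg_shares",
]

MIN_CLUSTER_SIZE = 20


@dataclass
class ConsensusClustering:
    k: int
    assignment: dict[str, int]  # gene -> retained cluster label (1-based)
    consensus_matrix: pd.DataFrame
    dropped: list[list[str]]  # gene lists of sub-threshold clusters
    never_cosampled: int = 0  # pairs with zero co-sampling occurrences
    delta_area: dict[int, float] = field(default_factory=dict)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, c in self.assignment.items():
            out.setdefault(c, []).append(g)
        return {c: sorted(gs) for c, gs in out.items()}


def _corr_distance(X: np.ndarray) -> np.ndarray:
    r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    d = (d + d.T) / 2.0
    np.clip(d, 0.0, 2.0, out=d)
    return d


def _cdf_area(consensus_vals: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries on [0, 1]."""
    x = np.sort(consensus_vals)
    n = x.size
    if n == 0:
        return 0.0
    # stepwise CDF integrated over [0, 1]
    cdf = np.arange(1, n + 1) / n
    area = 0.0
    prev_x = 0.0
    prev_cdf = 0.0
    for xi, ci in zip(x, cdf):
        area += prev_cdf * (xi - prev_x)
        prev_x, prev_cdf = xi, ci
    area += prev_cdf * (1.0 - prev_x)
    return float(area)


def consensus_cluster(
    study: ExpressionStudy,
    genes: Sequence[str],
    iterations: int = 100,
    subsample: float = 0.8,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    seed: int = 0,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    condition: str | None = None,
) -> ConsensusClustering:
    """Subsampled hierarchical consensus clustering of gene profiles."""
    genes = sorted(dict.fromkeys(getattr(genes, "genes", genes)))
    n = len(genes)
    if n < 25:
        raise ValidationError("consensus clustering needs at least 25 genes")
    if max(k_range) >= n:
        raise ValidationError("k_range exceeds the number of genes")
    rng = np.random.default_rng(seed)
    X = study.log2_tpm(genes, study.samples_where(condition)).values
    D = _corr_distance(X)

    m = max(2, int(round(subsample * n)))
    # one subsample draw per iteration, shared across all k so the k-selection
    # statistic compares like with like
    draws = [np.sort(rng.choice(n, size=m, replace=False)) for _ in range(iterations)]

    cosample = np.zeros((n, n))
    cocluster = {k: np.zeros((n, n)) for k in k_range}
    for idx in draws:
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="average")
        np.add.at(cosample, np.ix_(idx, idx), 1.0)
        for k in k_range:
            labels = fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            np.add.at(cocluster[k], np.ix_(idx, idx), same.astype(float))

    iu = np.triu_indices(n, k=1)
    never = int((cosample[iu] == 0).sum())
    if never:
        logger.warning("%d gene pairs were never co-sampled; consensus set to 0.5", never)

    consensus = {}
    areas = {}
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(cosample > 0, cocluster[k] / np.maximum(cosample, 1), 0.5)
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        areas[k] = _cdf_area(M[iu])

    ks = sorted(k_range)
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else areas[k]
    best_k = max(ks, key=lambda k: (delta[k], -k))

    M = consensus[best_k]
    Z = linkage(squareform(1.0 - M, checks=False), method="average")
    labels = fcluster(Z, t=best_k, criterion="maxclust")

    assignment: dict[str, int] = {}
    dropped: list[list[str]] = []
    next_label = 1
    for c in sorted(set(labels)):
        members = [genes[i] for i in np.flatnonzero(labels == c)]
        if len(members) < min_cluster_size:
            dropped.append(sorted(members))
            continue
        for g in members:
            assignment[g] = next_label
        next_label += 1

    return ConsensusClustering(
        k=best_k,
        assignment=assignment,
        consensus_matrix=pd.DataFrame(M, index=genes, columns=genes),
        dropped=dropped,
        never_cosampled=never,
        delta_area=delta,
    )


@dataclass
class ClusterActivity:
    """Per-sample PC1 activity of one gene cluster, sign-oriented."""

    cluster_id: str
    scores: pd.Series  # indexed by sample id
    sign_flipped: bool
    variance_explained: float


def cluster_activity(study: ExpressionStudy, cluster: Sequence[str],
                     cluster_id: str = "cluster",
                     condition: str | None = None) -> ClusterActivity:
    """PC1 of a gene cluster across samples, oriented positively.

    PCA is run on centered log2(TPM+1), samples x genes.  If more than half
    of the cluster genes correlate negatively with PC1, the scores are
    negated (a tie does not flip, for determinism).
    """
    cluster = sorted(dict.fromkeys(cluster))
    samples = study.samples_where(condition)
    if len(samples) < 3:
        raise ValidationError("cluster activity needs at least 3 samples")
    X = study.log2_tpm(cluster, samples).values.T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(Xc) > 1e-12):
        raise DegenerateClusterError(f"cluster {cluster_id!r} has zero expression variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, 0] * S[0]
    var_explained = float(S[0] ** 2 / np.sum(S**2))

    sds = Xc.std(axis=0)
    valid = sds > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.array([
            np.corrcoef(scores, Xc[:, j])[0, 1] if valid[j] else np.nan
            for j in range(Xc.shape[1])
        ])
    n_neg = int(np.nansum(corr < 0))
    n_valid = int(valid.sum())
    flipped = n_neg > n_valid / 2
    if flipped:
        scores = -scores
    return ClusterActivity(
        cluster_id=cluster_id,
        scores=pd.Series(scores, index=samples),
        sign_flipped=bool(flipped),
        variance_explained=var_explained,
    )


def _r2_of(y: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return 0.0
    Xd = np.column_stack([X, np.ones(y.size)])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0


def lmg_shares(y: np.ndarray, X: pd.DataFrame) -> dict[str, float]:
    """Exact LMG relative importance of each predictor column of X.

    The LMG share of predictor j is its marginal R² contribution averaged
    over all orderings of the predictors, computed here via the equivalent
    subset-weighted (Shapley) form.  Shares sum to the full-model R².
    """
    names = list(X.columns)
    p = len(names)
    if p > 8:
        raise ValidationError("exact LMG is limited to 8 predictors")
    cols = {name: X[name].to_numpy(dtype=float) for name in names}
    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, p + 1):
        for sub in itertools.combinations(names, r):
            key = frozenset(sub)
            r2_cache[key] = _r2_of(y, np.column_stack([cols[s] for s in sub]))
    shares = {}
    for j in names:
        others = [s for s in names if s != j]
        total = 0.0
        for r in range(0, p):
            w = math.factorial(r) * math.factorial(p - r - 1) / math.factorial(p)
            for sub in itertools.combinations(others, r):
                key = frozenset(sub)
                total += w * (r2_cache[key | {j}] - r2_cache[key])
        shares[j] = total
    return shares


@dataclass
class AttributionResult:
    response: str
    selected_predictors: list[str]
    coefficients: np.ndarray  # selected order, intercept last
    pvalues: np.ndarray
    r2: float
    r2_adjusted: float
    lmg_shares: dict[str, float]
    cv_r2: list[float] | None = None
    dropped_collinear: list[str] = field(default_factory=list)


def forward_select(
    y: np.ndarray,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    condition_threshold: float = 1e8,
) -> tuple[list[str], object, list[str]]:
    """Forward selection maximising adjusted R² under coefficient significance.

    At each step the candidate with the largest adjusted-R² gain whose own
    coefficient is significant at ``alpha`` joins the model; selection stops
    when no candidate improves adjusted R².  Candidates making the design
    ill-conditioned (collinear with earlier entrants) are skipped and logged.
    Returns (selected names, final OLS result or None, dropped-collinear).
    """
    selected: list[str] = []
    dropped: list[str] = []
    remaining = list(candidates.columns)
    current_adj = -np.inf
    best_res = None
    while remaining:
        gains = []
        for name in remaining:
            trial = selected + [name]
            X = np.column_stack([candidates[trial].to_numpy(), np.ones(y.size)])
            if np.linalg.cond(X) > condition_threshold:
                if name not in dropped:
                    dropped.append(name)
                continue
            res = sm.OLS(y, X).fit()
            p_new = res.pvalues[len(trial) - 1]
            if not (np.isfinite(p_new) and p_new < alpha):
                continue
            gains.append((float(res.rsquared_adj), name, res))
        if not gains:
            break
        gains.sort(key=lambda g: (-g[0], g[1]))
        gain_adj, name, res = gains[0]
        if gain_adj <= current_adj:
            break
        selected.append(name)
        remaining.remove(name)
        current_adj = gain_adj
        best_res = res
    if dropped:
        logger.info("collinear candidates skipped: %s", dropped)
    return selected, best_res, dropped


def attribute_activity(
    response: ClusterActivity,
    receptors: pd.DataFrame | None = None,
    nucsynth_score: pd.Series | None = None,
    others: Sequence[ClusterActivity] = (),
    alpha: float = 0.05,
) -> AttributionResult:
    """Explain a cluster's PC1 activity by receptors, dNTP synthesis, and peers.

    ``receptors`` is a samples x receptor-genes frame of log2(TPM+1) (or any
    aligned expression measure); all predictors are aligned on the response's
    samples.  Forward selection picks the model; exact LMG shares quantify
    each selected predictor's contribution to R².
    """
    y = response.scores
    frames = []
    if receptors is not None:
        frames.append(receptors.loc[y.index])
    if nucsynth_score is not None:
        frames.append(nucsynth_score.loc[y.index].rename("dntp_synthesis").to_frame())
    for other in others:
        frames.append(other.scores.loc[y.index].rename(f"PC1:{other.cluster_id}").to_frame())
    if not frames:
        raise ValidationError("no candidate predictors supplied")
    candidates = pd.concat(frames, axis=1)

    selected, res, dropped = forward_select(y.to_numpy(), candidates, alpha=alpha)
    if not selected or res is None:
        return AttributionResult(
            response=response.cluster_id, selected_predictors=[],
            coefficients=np.array([float(np.mean(y))]), pvalues=np.array([np.nan]),
            r2=0.0, r2_adjusted=0.0, lmg_shares={}, dropped_collinear=dropped,
        )
    shares = lmg_shares(y.to_numpy(), candidates[selected])
    return AttributionResult(
        response=response.cluster_id,
        selected_predictors=selected,
        coefficients=np.asarray(res.params),
        pvalues=np.asarray(res.pvalues),
        r2=float(res.rsquared),
        r2_adjusted=float(res.rsquared_adj),
        lmg_shares=shares,
        dropped_collinear=dropped,
    )


def cv_validate(
    response: ClusterActivity,
    predictors: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    holdout: bool = False,
    n_estimators: int = 200,
) -> list[float]:
    """Out-of-fold R² of a random-forest regression of activity on predictors.

    With ``holdout=True`` a single seeded 80/20 train/test split is scored
    instead (the independent-dataset protocol); otherwise ``folds``-fold CV.
    """
    y = response.scores.to_numpy()
    X = predictors.loc[response.scores.index].to_numpy()
    if holdout:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(y.size)
        cut = int(round(0.8 * y.size))
        train, test = idx[:cut], idx[cut:]
        model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
        model.fit(X[train], y[train])
        return [float(model.score(X[test], y[test]))]
    if y.size < folds * 3:
        raise ValidationError(f"need at least {folds * 3} samples for {folds}-fold CV")
    scores = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
        model.fit(X[train], y[train])
        scores.append(float(model.score(X[test], y[test])))
    return scores


def load_dntp_synthesis_genes() -> list[str]:
    """Bundled de novo deoxyribonucleotide-synthesis gene symbols."""
    text = resources.files("ador").joinpath("data/dntp_synthesis_genes.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def nucleotide_synthesis_score(study: ExpressionStudy,
                               genes: Sequence[str] | None = None,
                               condition: str | None = None) -> pd.Series:
    """Per-sample dNTP-synthesis activity: mean centered log2(TPM+1)."""
    if genes is None:
        genes = load_dntp_synthesis_genes()
    genes = [g for g in genes if g in study.tpm.index]
    if not genes:
        raise ValidationError("none of the score genes are present in the study")
    L = study.log2_tpm(genes, study.samples_where(condition))
    centered = L.sub(L.mean(axis=1), axis=0)
    return centered.mean(axis=0)
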