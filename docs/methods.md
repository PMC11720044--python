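# Methods

## The model

The toolkit treats a cancer type's age-dependent occurrence rate y(x) as the
product of two necessary conditions: enough accumulated opportunity for a
transformed clone to exist (risk), and enough circulating growth signal for
it to keep proliferating (support).

**Risk.** The risk level at age x is the cumulative number of stem-cell
divisions in the host organ, SCD(x) = Σ_{n=1..⌊log2 s⌋} 2ⁿ + s·x·d_yr: a
developmental term counting the doublings from one precursor cell to an
organ of s stem cells (equal to 2s−2 when s is a power of two; the floor is
used for non-integral log2 s, the conservative reading of an integer-indexed
sum), plus turnover at d_yr divisions per stem cell per year.  Raw SCD spans
roughly 1e8–1e12 and is scaled by 1e9 by default.  SCD is affine in age, so
the fitted risk curve f1 is exact under a linear basis.  For sites with no
published kinetics, an externally supplied risk-by-age series can stand in
(`risk_curve_from_series`).

**Support.** A signal's circulating availability at age x is the weighted
sum over producing organs, Σ ω·L(organ, x), with ω = 1.0 (major) or 0.5
(minor).  Brain sources other than the hypothalamus are excluded — the
blood–brain barrier keeps their product out of circulation.  Non-protein
hormones (e.g. estradiol) take a measured serum series instead.  Fitted
support curves must pass R² > 0.6 with p < 0.05 to be used.

**Regression.** Candidate terms are the intercept, each curve as a main
effect, and risk×signal (and risk×infection) products — the smallest space
containing every model shape the framework uses.  Every subset of at most
`max_terms` (default 5) non-intercept terms is fitted by OLS; subsets with
any non-intercept coefficient at p ≥ α (default 0.05) are discarded; the
admissible subset with the highest adjusted R² wins, ties resolved to fewer
terms then lexicographic ids, making the output independent of enumeration
and observation order.  Intercept-only is never reported as a model: a
response explained by nothing yields a `NoSignificantModelError` carrying
the best inadmissible fit for inspection.  Exhaustive enumeration is capped
at 8 candidate terms; the problem sizes here (a risk curve plus one to three
signals) stay far below the cap.

## Curve fitting and modality

Registry tables give rates at a handful of ages; a continuous approximation
is fitted by scanning polynomial bases in age and in log(age+1), degrees
0–5, selected by adjusted R² (ties to fewer coefficients).  Degree 0 is
included so constant data resolve to a constant.  Evaluation outside the
observed age range is clamped to the boundary value: low-degree polynomials
extrapolate violently and a spurious out-of-range mode would corrupt
modality calls.  Confidence bands are pointwise confidence intervals of the
mean curve (not prediction intervals).

Modes are local maxima of the curve on a regular grid (default 1 year).
Boundary maxima count — a rate still rising at the oldest observed age is a
right-boundary mode.  Two numerical guards matter in practice: maxima closer
than `min_separation` (default 5 years, one registry bin) are merged, and
maxima whose topographic prominence is below `min_prominence` (default 5 %)
of the curve's value range are discarded, because polynomial fits ripple at
sub-percent amplitude near the domain edges and such wiggle is not an
incidence mode.  Sharply bimodal shapes need more flexibility than degree 5
over a 70-year window; modality analyses of bimodal series therefore pass
`max_degree=8`.  `detect_modes` also accepts a raw series (linear
interpolation): at 1 % noise a flat-topped peak can then split into twin
maxima a few years apart, which the 5-year merge usually, but not always,
absorbs.

## Viral decomposition

With fcv(x) the conditional infection probability among patients, the
observed rate splits exactly: y_v = y·fcv, y_nv = y·(1−fcv); conservation
y_v + y_nv = y holds pointwise by construction.  fcv is estimated from
patient metadata in 5-year age bins; bins with fewer than 5 patients take
the mean of their nearest populated neighbours (one-sided at the
boundaries); bin fractions are fitted to a continuous curve whose evaluated
values are clipped to [0, 1] (clipping, not constrained refitting).
Population background curves apply the marker logic per virus — HBV requires
surface antigen *and* core antibody, HCV requires detectable RNA, HPV uses
the 16/18 flag — optionally stratified by sex.

A caution discovered during validation: multiplicative decomposition
amplifies the *absolute* error of fcv wherever y is large.  A global
polynomial cannot hold fcv exactly at zero across a long tail; its
±0.02–0.05 ripple, multiplied by old-age rates of several hundred per
100,000, can leak a spurious late mode into the infection-attributable
component.  When per-age fractions are known or well estimated,
`InfectionCurve.from_series` interpolates them piecewise-linearly and avoids
the leakage; the fitted route remains appropriate for smooth, non-vanishing
infection curves.  Slowly varying population rates over ~13 bins are best
fitted with low degree (≤ 2–3); higher degrees can cross at the boundaries
between sex-stratified curves purely through fit wiggle.

## Signal discovery

Co-expression is Pearson correlation on log2(TPM+1) profiles; an edge
requires PCC strictly above 0.3 (one-sided: anti-correlation never links)
with Benjamini–Hochberg FDR below 0.05, the BH family being all pairs tested
in one invocation (receptor–core tests share one family per receptor).  The
core-gene filter removes, each round simultaneously, all genes with
within-set degree < N (default 10) until a fixpoint — simultaneous removal
makes the result order-independent — then drops the ⌊count/3⌋ lowest-degree
survivors, ties resolved by lexicographic gene id.  Note that under a
near-complete planted block the degrees tie almost everywhere and the
lexicographic tie-break then decides *which* genes go; this is deterministic
but arbitrary, as any tie-break must be.  Driver-signal gates: receptor mean
TPM > 5 across tumors, ≥ 1.5-fold upregulation on mean TPM with pseudocount
1 (the estimator for the fold gate is a design choice; a median-based log2
fold change plus rank-sum test with BH FDR is used by the synthetic DE
stand-in), and co-expression with ≥ 10 % of the core set; only bloodborne
ligands are retained, a ligand qualifying if any of its receptors passes.

## Cluster attribution

Consensus clustering runs average-linkage hierarchical clustering (distance
1 − PCC) 100 times on random 80 % gene subsamples, shared across the k
scan so the selection statistic compares like with like; the consensus
matrix is the fraction of co-sampled iterations in which a pair co-clusters
(pairs never co-sampled are flagged and set to 0.5, not treated as zero
evidence — with 100 iterations at 80 % this is practically unreachable).
k ∈ 2..6 is chosen by the largest relative increase in the area under the
consensus CDF, ties to smaller k; final labels come from clustering
1 − consensus at that k; clusters under 20 genes are dropped and recorded.

Cluster activity is PC1 of centered log2(TPM+1) over the member genes,
negated when more than half the members correlate negatively with it (an
exact tie does not flip, for determinism).  Attribution is forward-selection
OLS — each step adds the candidate with the largest adjusted-R² gain whose
own coefficient is significant, stopping when no candidate improves;
candidates that would make the design ill-conditioned are skipped and
logged.  LMG importance is computed exactly by the subset-weighted (Shapley)
form of the all-orderings average, so shares sum to the full-model R² to
machine precision; exact computation is limited to 8 predictors.
Generalisation is checked by seeded 10-fold random-forest CV (out-of-fold
R²), with an 80/20 holdout mode for independent-dataset protocols.  The
bundled de novo deoxyribonucleotide-synthesis gene set (data/) is a curated
list of standard pathway members used for the per-sample synthesis score
(mean centered log2(TPM+1)).

## Gender and iron

fd(x) = log2(male/female rate) is defined only where both rates are
positive; excluded ages are reported.  Iron-gene fold changes use medians
with pseudocount 1, which keeps all-zero bins finite and shrinks fold
changes toward zero as a common baseline grows.  The ratio model reuses the
forward-selection engine; a single hormone fold-change column gives the
one-predictor variant.  The permutation test reassigns the n+m labels as a
permutation (group sizes preserved) and counts permuted cancer-group means
*strictly* exceeding the observed mean; p = count/iterations exactly as the
estimator is defined — ties count against significance and p = 0 is
possible; `smoothed=True` gives (count+1)/(iterations+1) for users needing a
never-zero p.  Wilcoxon rank-sum comparisons are two-sided per age bin with
conventional star codes; identical male/female samples short-circuit to
p = 1.

## Synthetic data: what it emulates, and what it does not

The generators are the package's study conditions, seeded and fully
recorded in truth objects.

* `simulate_ador_study` builds rates exactly as the model family assumes:
  β0 + Σ β·term(x) + N(0, σ), σ defaulting to 1 % of the noiseless range,
  truncated at zero.  The default signal shapes are a Gaussian bump peaking
  at 40 (hormones that peak in early adulthood and decline) and a logistic
  cliff at 78; together with the affine risk term and the intercept they
  span four nearly orthogonal age patterns.  That orthogonality is a design
  requirement, not a convenience: with monotone shapes the candidate terms
  are so collinear that no coefficient can be pinned to 5 % at 1 % noise
  (the per-coefficient z-margins cap near 1.5); the chosen design has
  margins ≥ 3.2.  The intercept (580 per 100,000) is large because its
  standard error is fixed by the design geometry, so only a large intercept
  is recoverable to 5 % — rates of 190–940 per 100,000 are stylised-high
  but within the range of common-cancer incidence.  The bimodal variant
  adds an infection-attributable component risk(x)·bump(38, 9) to a base
  that rises via a logistic signal to a right-boundary peak at 90
  (late-onset pattern); monotone base shapes keep the polynomial fits
  ripple-free, and the generating fcv is recorded alongside.
* `simulate_expression_study` plants one latent factor per co-expression
  cluster on the log2 scale with multiplicative (log-normal) noise —
  matching the analysis scale — receptor genes as noisy linear readouts of
  a designated factor, tumor-only and male-only log2 shifts, and a count
  layer by multinomial draws at fixed depth.  TPM-like values are not
  renormalised to 1e6 per sample: the simulated panel is a gene subset, not
  a transcriptome.
* `simulate_cohort` draws infection per virus from a logistic model in age
  with a male offset, writes HBV serology with a concordance parameter plus
  a small stray-single-marker rate (so the both-markers rule has something
  to reject), and log-normal analytes with sex and age shifts; cancer
  labels can shift ferritin by a chosen log2 amount.

What passing on these conditions does *not* show: real incidence curves are
not exact β-combinations of smooth curves (cohort effects, screening
artifacts, registry binning); real expression has batch structure, library
composition and zero inflation beyond log-normal noise; real serology has
assay error beyond a concordance parameter.  The closed loops certify the
estimators and selection machinery, not the biological claims.

## Problem sizes

Test and acceptance runs use 71-point age grids, expression studies of
40–120 genes × 150–200 samples, cohorts of 2,000–10,000, 100-replicate
recovery loops, 20-seed discovery loops, 10-seed clustering loops, and
2,000-iteration permutation calibration over 200 replicate cohorts (the
100,000-iteration default of the permutation test is kept for single
analyses).  The full suite runs in well under a minute on one CPU.
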