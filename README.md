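# ador — modelling age-dependent cancer occurrence rates

Cancer registries report, for each cancer type, the occurrence rate per
100,000 as a function of age at diagnosis — the age-dependent occurrence
rate (ADOR).  Most solid tumors show a *unimodal* ADOR: the rate climbs to a
peak age and then falls, even though mutation burden, immune decline and
chronic inflammation all keep rising with age.  A few types (liver, cervix)
are *bimodal*, with an extra early peak.  `ador` is a toolkit for
epidemiologists and computational biologists who want to explain these
shapes quantitatively:

* **Risk**: the cumulative number of stem-cell divisions (SCD) in the host
  organ from the first precursor cell to age *x*,

  ```
  SCD(x) = Σ_{n=1..⌊log2 s⌋} 2^n + s · x · d_yr      (≈ 2s − 2 + s·x·d_yr)
  ```

  for an organ of `s` stem cells turning over `d_yr` times a year (scaled by
  10⁻⁹), tabulated as a curve `f1(x)`.

* **Support**: the age-dependent circulating availability of the growth
  signals (hormones, growth factors) a cancer type specifically requires,
  estimated per signal as `Σ_organs ω·L(organ, x)` with ω = 1 for major and
  0.5 for minor producing organs (brain sources excluded, hypothalamus
  excepted), fitted as curves `f2(x), f3(x), …` and gated at R² > 0.6,
  p < 0.05.  Which signals a cancer needs is predicted from expression data:
  a bloodborne ligand qualifies when a receptor is expressed (mean TPM > 5
  in tumors), ≥ 1.5-fold upregulated vs. control, and co-expressed (PCC >
  0.3, FDR < 0.05) with ≥ 10 % of the core cell-cycle genes.

* **Model**: exhaustive all-subsets OLS of the ADOR on
  `{f1, f_i, f1·f_i}` terms, keeping only models whose every coefficient is
  significant at α = 0.05 and choosing the best adjusted R²:

  ```
  y_p(x) = β0 + β1·f1(x) + Σ_i βi·f_i(x) + Σ_j γj·f1(x)·f_j(x)
  ```

* **Bimodality**: with `fcv(x)` the conditional probability of viral
  infection (HBV/HCV, HPV 16/18) among patients at age x, the observed rate
  splits exactly as `y_v = y·fcv` and `y_nv = y·(1−fcv)`; each component is
  unimodal and modelled as above.

* **Cell-cycle program structure**: core cell-cycle genes (iterative
  degree-≥N co-expression filter, bottom-third drop) are partitioned by
  subsampled consensus clustering (100 × 80 % hierarchical, distance
  1 − PCC, clusters < 20 genes dropped); each cluster's activity is its
  sign-oriented PC1 and is attributed to receptors, a de novo
  deoxyribonucleotide-synthesis score and peer clusters via forward
  selection with exact LMG importance shares and random-forest
  cross-validation.

* **Gender disparity**: `fd(x) = log2(male rate / female rate)` is regressed
  on per-age iron-gene expression fold changes
  `log2((median_male+1)/(median_female+1))`; serum iron analytes are
  compared by sex with Wilcoxon tests, and the ferritin–cancer association
  is tested by 100,000 group-label permutations with
  `p = #{permuted mean > observed mean} / 100,000`.

Registry, tumor-expression and population-serology extracts are not
bundled; a seeded `synthetic_data` module generates inputs with the same
statistical structure (and records the generating truth), so the entire
pipeline runs and is tested offline.

## Worked example

```bash
python examples/02_risk_support_regression.py
```

prints

```
organ: s=1.07e+09 stem cells, d_yr=6.0 divisions/year
scaled SCD at age 20: 131.0, at 80: 517.5
candidate terms: ['1', 'risk', 'sig_a', 'sig_b', 'risk*sig_a', 'risk*sig_b']
selected terms:  ['risk', 'sig_b', 'risk*sig_a']
  risk           beta=   -0.7067  p=3.77e-66
  sig_b          beta=    4.0012  p=9.92e-68
  risk*sig_a     beta=    0.0054  p=2.89e-67
  intercept      beta=  582.7112  p=7.33e-73
adjusted R2 = 0.9993  (generating betas: {'risk': -0.7, 'sig_b': 4.0, 'risk*sig_a': 0.0055}, intercept 580.0)
```

The generated incidence series was built from a known β-combination of the
risk curve and two signal curves plus 1 % noise; the all-subsets search
recovers exactly the generating terms and coefficients, with every
coefficient individually significant.  The other scripts in `examples/`
walk through curve fitting and peak detection, bimodal decomposition by
infection status, the cell-cycle cluster pipeline, and the gender/iron
analyses, each printing the numbers it computes and what they mean.

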