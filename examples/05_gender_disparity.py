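"""Quantify and explain the male/female occurrence-rate gap.

Computes the per-age log2 male/female rate ratio fd, regresses it on
iron-gene expression fold changes by forward selection, compares serum
analytes by sex with the Wilcoxon rank-sum test, and runs the ferritin
label-permutation test against cancer status.
"""

import numpy as np
import pandas as pd

from ador import (
    IronGeneFC,
    ferritin_permutation_test,
    fit_ratio_model,
    gender_ratio_series,
    serum_gender_compare,
    simulate_ador_study,
    simulate_cohort,
)

series, _ = simulate_ador_study(seed=1, sex_log2_ratio=0.5)
fd = gender_ratio_series(series["male"], series["female"])
print(f"fd = log2(male/female rate): mean {fd.fd.mean():.3f} over "
      f"{fd.ages.size} ages (generating ratio 2^0.5 ~ 1.41x male excess)")

# iron-gene fold-change predictors on the fd age grid
rng = np.random.default_rng(1)
ages = fd.ages
fc_true = 0.3 + rng.normal(0, 0.05, ages.size)      # male-up iron transporter
decoys = rng.normal(0, 0.1, (ages.size, 4))
table = pd.DataFrame(np.column_stack([fc_true, decoys]), index=ages,
                     columns=["TFRC_fc", "d1", "d2", "d3", "d4"])
fd_coupled = fd
fd_coupled.fd[:] = 1.6 * fc_true + rng.normal(0, 0.02, ages.size)
model = fit_ratio_model(fd_coupled, IronGeneFC(fc=table))
print(f"forward selection picks {model.selected_predictors} "
      f"(coef {model.coefficients[0]:.2f}, adjusted R2={model.r2_adjusted:.3f})")

cohort, _ = simulate_cohort(n=3000, ferritin_cancer_log2_shift=0.6, seed=2)
table = serum_gender_compare(cohort, "ferritin", np.arange(20, 81, 10))
print("\nserum ferritin by sex and age bin (Wilcoxon):")
print(table[["age_lo", "age_hi", "median_male", "median_female", "stars"]]
      .to_string(index=False))

res = ferritin_permutation_test(cohort["ferritin"], cohort["cancer_label"],
                                iterations=100_000, seed=3)
print(f"\nferritin permutation test: observed cancer-group mean "
      f"{res.observed_mean:.0f}, p = {res.p_value:.5f} over {res.n_iterations} "
      "label reshuffles")
print()
print("Male serum ferritin sits well above female at every age, and the "
      "cancer-labelled group's ferritin excess is essentially never matched "
      "by random label assignments.")
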