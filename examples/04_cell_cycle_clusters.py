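"""From a cell-cycle gene list to driver signals and cluster attribution.

Filters a curated gene list to its co-expressed core, predicts which
bloodborne ligands drive the program, partitions the core into consensus
co-expression clusters, summarises each cluster as a sign-oriented PC1, and
attributes cluster activity to receptor expression with exact LMG shares
and random-forest cross-validation.
"""

import numpy as np
import pandas as pd

from ador import (
    attribute_activity,
    cluster_activity,
    consensus_cluster,
    cv_validate,
    filter_core_cycle_genes,
    predict_driver_signals,
    simulate_expression_study,
)

# two co-expressed programs, each driven by its own receptor; LIG_C/RCPC is
# an uncoupled decoy that must not be called a driver
study, truth = simulate_expression_study(
    cluster_sizes=(60, 60), n_noise_genes=10, n_samples=200,
    within_cluster_sigma=0.5,
    receptor_couplings={"RCPA": ("C1", 1.0, 0.5), "RCPB": ("C2", 0.8, 0.5),
                        "RCPC": ("C1", 0.0, 1.0)},
    condition_log2fc={"RCPA": 1.2, "RCPB": 1.2, "RCPC": 1.2}, seed=1)

seed_genes = truth.clusters["C1"] + truth.clusters["C2"] + truth.noise_genes
core = filter_core_cycle_genes(study, seed_genes, N=10)
print(f"curated list: {len(seed_genes)} genes -> core set: {len(core)} genes "
      f"({core.provenance['fixpoint_rounds']} filter rounds, "
      f"{len(core.provenance['bottom_dropped'])} dropped in the bottom third)")

annotations = pd.DataFrame({"ligand": ["LIG_A", "LIG_B", "LIG_C"],
                            "receptor": ["RCPA", "RCPB", "RCPC"],
                            "bloodborne": [True, True, True]})
signals = predict_driver_signals(core, study, annotations)
for s in signals:
    print(f"candidate driver: {s.ligand} via {s.receptors} "
          f"(mean TPM {s.receptor_mean_tpm:.0f}, fold change "
          f"{s.receptor_fold_change:.1f}, co-expressed with "
          f"{100 * s.core_coexpression_fraction:.0f}% of the core)")

cc = consensus_cluster(study, core.genes, seed=1)
clusters = cc.clusters()
print(f"consensus clustering: k={cc.k}, cluster sizes "
      f"{ {c: len(g) for c, g in clusters.items()} }")

acts = {c: cluster_activity(study, genes, f"cluster{c}")
        for c, genes in clusters.items()}
resp = acts[1]
receptors = study.log2_tpm(["RCPA", "RCPB", "RCPC"]).T
others = [a for c, a in acts.items() if c != 1]
attr = attribute_activity(resp, receptors=receptors, others=others)
print(f"cluster 1 activity (PC1, {100 * resp.variance_explained:.0f}% variance) "
      f"explained by: {attr.selected_predictors}, adjusted R2={attr.r2_adjusted:.3f}")
for name, share in attr.lmg_shares.items():
    print(f"  LMG share of {name}: {share:.3f}")

predictors = pd.concat(
    [receptors] + [o.scores.rename(f"PC1:{o.cluster_id}").to_frame() for o in others],
    axis=1)
cv = cv_validate(resp, predictors[attr.selected_predictors], folds=10, seed=1)
print(f"10-fold random-forest CV R2: mean {np.mean(cv):.3f}, min {min(cv):.3f}")
print()
print("Each program's coupled receptor dominates its cluster's activity, "
      "the uncoupled decoy is rejected, and the relationship generalises "
      "across folds.")
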