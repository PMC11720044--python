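"""Explain an incidence curve by risk and growth-signal support.

The risk side is cumulative stem-cell divisions (SCD) in the host organ;
the support side is the age-dependent circulating availability of the
growth signals the cancer type needs.  All-subsets regression with
risk x signal interaction terms selects the best fully-significant model.
"""

from ador import (
    OrganKinetics,
    all_subsets_fit,
    build_term_set,
    risk_curve,
    scd_at_age,
    simulate_ador_study,
)

series, truth = simulate_ador_study(seed=1)
organ = truth.organ

print(f"organ: s={organ.s:.3g} stem cells, d_yr={organ.d_yr} divisions/year")
print(f"scaled SCD at age 20: {scd_at_age(organ, 20):.1f}, at 80: {scd_at_age(organ, 80):.1f}")

risk = risk_curve(organ, series["both"].ages)
signals = list(truth.signal_curves().items())
terms = build_term_set(risk, signals, series["both"].ages)
model = all_subsets_fit(series["both"], terms, max_terms=5)

print(f"candidate terms: {terms.term_ids}")
print(f"selected terms:  {model.selected_terms}")
for term, coef, p in zip(model.selected_terms + ["intercept"],
                         model.coefficients, model.pvalues):
    print(f"  {term:14s} beta={coef:10.4f}  p={p:.2e}")
print(f"adjusted R2 = {model.r2_adjusted:.4f}  "
      f"(generating betas: {truth.betas}, intercept {truth.intercept})")
print()
print("The selected model matches the generating combination: a negative "
      "risk main effect, a late-dropping support signal, and the "
      "risk x early-adult-signal product that shapes the mid-life peak.")
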