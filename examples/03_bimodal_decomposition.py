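"""Split a bimodal incidence curve by viral-infection status.

A bimodal rate series is generated (early infection-driven peak plus a late
supported peak), the conditional infection probability among patients is
estimated from simulated per-patient infection labels, and the series is
decomposed into y_v = y * fcv and y_nv = y * (1 - fcv).
"""

import numpy as np
import pandas as pd

from ador import (
    conditional_infection_curve,
    decompose_ador,
    detect_modes,
    fit_age_curve,
    simulate_ador_study,
)

series, truth = simulate_ador_study(seed=1, bimodal=True)
y = series["both"]

total_modes = detect_modes(fit_age_curve(y, max_degree=8))
print(f"total series: {total_modes.n_modes} modes at ages "
      f"{[f'{a:.0f}' for a in total_modes.peak_ages]}")

# per-patient infection labels drawn from the true conditional probability
rng = np.random.default_rng(1)
draws = 400
patients = pd.DataFrame({
    "age": np.repeat(truth.ages, draws),
    "infected": (rng.random((truth.ages.size, draws))
                 < truth.fcv_values[:, None]).astype(float).ravel(),
})
fcv_fit = conditional_infection_curve(patients, virus="HBV")
print(f"fitted fcv(40) = {fcv_fit(40.0):.2f}, fcv(75) = {fcv_fit(75.0):.2f} "
      "(infection probability among patients)")

# decompose with the binned fractions interpolated directly: a global
# polynomial's small tail ripple would be amplified by the large old-age
# rates and leak mass into the infection component
from ador.viral_decomposition import InfectionCurve
fractions = patients.groupby("age")["infected"].mean()
fcv = InfectionCurve.from_series(fractions.index.to_numpy(),
                                 fractions.to_numpy(), virus="HBV")
parts = decompose_ador(y, fcv)
m_inf = detect_modes(parts.with_infection)
m_free = detect_modes(parts.without_infection)
err = np.abs(parts.with_infection.values + parts.without_infection.values - y.values).max()
print(f"infection-attributable component: peak at {m_inf.peak_ages[0]:.0f}")
print(f"infection-free component:         peak at {m_free.peak_ages[0]:.0f}")
print(f"conservation |yv + ynv - y| max: {err:.1e}")
print()
print("The early peak of the bimodal curve is carried entirely by the "
      "infection-attributable component; what remains is a unimodal curve "
      "explainable by risk and support alone.")
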