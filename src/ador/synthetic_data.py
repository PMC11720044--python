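"""Seeded synthetic inputs with the statistical structure the analyses assume.

Registry extracts, tumor/normal expression compendia and population serology
tables cannot be bundled, so every pipeline stage is exercised on generated
data whose ground truth is recorded alongside:

* ``simulate_ador_study`` — occurrence-rate series built exactly as the model
  family assumes: a linear combination of the organ risk curve, declining
  signal-availability curves and risk x signal products, plus Gaussian noise,
  optionally with an early-age infection-attributable component that makes
  the total bimodal.
* ``simulate_expression_study`` — log-normal expression with planted
  co-expressed gene clusters (one latent factor per cluster), receptor genes
  that are noisy linear readouts of a designated factor, tumor fold-change
  effects, and a multinomial count layer.
* ``simulate_cohort`` — per-individual serum analytes (log-normal with sex
  and age shifts), viral serology drawn by the marker logic the analyses
  expect, and cancer labels optionally associated with ferritin.

Every generator is deterministic given its seed, and each returns a truth
object sufficient to recompute the expected outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .age_curves import AgeSeries
from .errors import ValidationError
from .risk_model import OrganKinetics, RiskCurve, risk_curve
from .signal_discovery import ExpressionStudy

__all__ = [
    "AdorTruth",
    "ExpressionTruth",
    "CohortTruth",
    "simulate_ador_study",
    "simulate_expression_study",
    "simulate_cohort",
]

DEFAULT_AGES = np.arange(20.0, 91.0)  # 20..90, 1-year grid

# default organ kinetics: a colon-scale stem-cell pool (2^30 cells, ~6
# divisions/year), giving raw SCD in the 1e9-1e12 range the scaling expects
DEFAULT_ORGAN = OrganKinetics(organ="synthetic-organ", s=float(2**30), d_yr=6.0)

# Default signal availabilities.  Non-polynomial shapes are essential: the
# risk curve is affine in age, so polynomial signal shapes would put every
# candidate regression term in one low-degree polynomial span and make the
# generating coefficients unidentifiable.  The defaults pair a hormone that
# peaks in early adulthood and declines (Gaussian bump, cf. DHEA-S or
# growth-hormone profiles) with one that stays high and drops steeply in
# old age (logistic cliff); together with the affine risk term and the
# intercept these span four nearly orthogonal age patterns, which is what
# makes coefficient recovery from noisy rates well-posed.  Each spec is
# (kind, params): ("exp", (A, tau)) -> A*exp(-age/tau);
# ("logistic", (A, x0, s)) -> A/(1+exp((age-x0)/s));
# ("gauss", (A, mu, sd)) -> A*exp(-(age-mu)^2/(2 sd^2)); ("poly", coefs).
DEFAULT_SIGNALS: dict[str, tuple[str, tuple[float, ...]]] = {
    "sig_a": ("gauss", (150.0, 40.0, 12.0)),
    "sig_b": ("logistic", (80.0, 78.0, 3.5)),
}

# default generating coefficients: the risk x signal product carries the
# unimodal shape (risk rises, support falls); rates stay positive over
# ages 20-90 and peak in mid-life (~41)
DEFAULT_BETAS: dict[str, float] = {
    "risk": -0.7,
    "sig_b": 4.0,
    "risk*sig_a": 0.0055,
}
DEFAULT_INTERCEPT = 580.0

# bimodal variant: the supported (infection-free) component rises to a
# right-boundary peak (late-onset disease), the infection-attributable
# component peaks early (~40).  A negative logistic scale gives the rising
# sigmoid; monotone shapes keep the polynomial fits ripple-free.
BIMODAL_SIGNALS: dict[str, tuple[str, tuple[float, ...]]] = {
    "sig_a": ("logistic", (150.0, 65.0, -6.0)),
}
BIMODAL_BETAS: dict[str, float] = {
    "risk*sig_a": 0.01,
}
BIMODAL_INTERCEPT = 60.0


def _signal_fn(spec: tuple[str, tuple[float, ...]]) -> Callable[[np.ndarray], np.ndarray]:
    kind, params = spec
    if kind == "exp":
        amp, tau = params
        return lambda ages: amp * np.exp(-np.asarray(ages, dtype=float) / tau)
    if kind == "logistic":
        amp, x0, s = params
        return lambda ages: amp / (1.0 + np.exp((np.asarray(ages, dtype=float) - x0) / s))
    if kind == "gauss":
        amp, mu, sd = params
        return lambda ages: amp * np.exp(-((np.asarray(ages, dtype=float) - mu) ** 2) / (2 * sd**2))
    if kind == "poly":
        return lambda ages: np.polyval(params, np.asarray(ages, dtype=float))
    raise ValidationError(f"unknown signal kind {kind!r}")


@dataclass
class AdorTruth:
    """Everything needed to recompute a simulated occurrence-rate study."""

    betas: dict[str, float]
    intercept: float
    organ: OrganKinetics
    risk: RiskCurve
    signal_specs: dict[str, tuple[str, tuple[float, ...]]]
    ages: np.ndarray
    noise_sigma: float
    seed: int
    sex_log2_ratio: float
    expected: np.ndarray  # noiseless sex-neutral rates
    bimodal: bool = False
    infection_beta: float = 0.0
    infection_curve_coefs: tuple[float, ...] = ()
    infection_component: np.ndarray | None = None
    base_component: np.ndarray | None = None
    fcv_values: np.ndarray | None = None

    def signal_curves(self) -> dict[str, Callable]:
        return {name: _signal_fn(spec) for name, spec in self.signal_specs.items()}

    def infection_shape(self) -> Callable:
        if not self.bimodal:
            raise ValidationError("study was generated without an infection component")
        mu, sd = self.infection_curve_coefs
        return lambda ages: np.exp(-((np.asarray(ages, float) - mu) ** 2) / (2 * sd**2))


def simulate_ador_study(
    ages: np.ndarray = DEFAULT_AGES,
    noise_sigma: float | None = None,
    seed: int = 0,
    betas: dict[str, float] | None = None,
    intercept: float | None = None,
    organ: OrganKinetics = DEFAULT_ORGAN,
    signal_specs: dict[str, tuple[str, tuple[float, ...]]] | None = None,
    sex_log2_ratio: float = 0.5,
    bimodal: bool = False,
    infection_beta: float = 1.0,
    infection_peak_age: float = 38.0,
    infection_peak_sd: float = 9.0,
) -> tuple[dict[str, AgeSeries], AdorTruth]:
    """Generate occurrence-rate series from the generative model the fits assume.

    Rates are beta0 + sum_i beta_i * term_i(age) + N(0, noise_sigma), truncated
    at 0.  ``noise_sigma`` defaults to 1% of the noiseless signal range.  With
    ``bimodal=True`` an infection-attributable component
    ``infection_beta * risk(age) * bump(age)`` (a Gaussian-bump infection-rate
    shape centred at ``infection_peak_age``) is added, moving the early peak in.
    Males and females share the shape, scaled by 2^(+-sex_log2_ratio/2).

    Returns ({'both','male','female'}: AgeSeries, AdorTruth).
    """
    ages = np.asarray(ages, dtype=float)
    if betas is None:
        betas = dict(BIMODAL_BETAS if bimodal else DEFAULT_BETAS)
    else:
        betas = dict(betas)
    if signal_specs is None:
        signal_specs = dict(BIMODAL_SIGNALS if bimodal else DEFAULT_SIGNALS)
    else:
        signal_specs = dict(signal_specs)
    if intercept is None:
        intercept = BIMODAL_INTERCEPT if bimodal else DEFAULT_INTERCEPT
    rng = np.random.default_rng(seed)

    risk = risk_curve(organ, ages)
    curves: dict[str, Callable] = {"risk": risk}
    curves.update({name: _signal_fn(spec) for name, spec in signal_specs.items()})

    base = np.full_like(ages, float(intercept))
    for term_id, beta in betas.items():
        parts = term_id.split("*")
        vals = np.ones_like(ages)
        for p in parts:
            if p not in curves:
                raise ValidationError(f"unknown curve {p!r} in beta term {term_id!r}")
            vals = vals * np.asarray(curves[p](ages), dtype=float)
        base = base + beta * vals

    infection_component = None
    fcv_values = None
    inf_coefs: tuple[float, ...] = ()
    total = base
    if bimodal:
        bump = np.exp(-((ages - infection_peak_age) ** 2) / (2 * infection_peak_sd**2))
        infection_component = infection_beta * np.asarray(risk(ages)) * bump
        total = base + infection_component
        with np.errstate(invalid="ignore", divide="ignore"):
            fcv_values = np.where(total > 0, infection_component / total, 0.0)
        inf_coefs = (infection_peak_age, infection_peak_sd)

    rng_range = float(total.max() - total.min())
    if noise_sigma is None:
        noise_sigma = 0.01 * rng_range
    if (total < 0).mean() > 0.10:
        raise ValidationError("config error: negative expected rates over >10% of the grid")

    noise = rng.normal(0.0, noise_sigma, size=ages.size) if noise_sigma > 0 else 0.0
    y = np.maximum(total + noise, 0.0)
    series = {
        "both": AgeSeries(ages, y, label="synthetic ADOR", sex="both"),
        "male": AgeSeries(ages, y * 2 ** (sex_log2_ratio / 2), label="synthetic ADOR", sex="male"),
        "female": AgeSeries(ages, y * 2 ** (-sex_log2_ratio / 2), label="synthetic ADOR", sex="female"),
    }
    truth = AdorTruth(
        betas=betas, intercept=intercept, organ=organ, risk=risk,
        signal_specs=signal_specs, ages=ages, noise_sigma=float(noise_sigma),
        seed=seed, sex_log2_ratio=sex_log2_ratio, expected=total,
        bimodal=bimodal, infection_beta=infection_beta if bimodal else 0.0,
        infection_curve_coefs=inf_coefs, infection_component=infection_component,
        base_component=base if bimodal else None, fcv_values=fcv_values,
    )
    return series, truth


@dataclass
class ExpressionTruth:
    clusters: dict[str, list[str]]  # cluster name -> member genes
    noise_genes: list[str]
    receptor_couplings: dict[str, tuple[str, float, float]]  # receptor -> (cluster, beta, sigma)
    condition_log2fc: dict[str, float]
    sex_log2fc: dict[str, float]
    factors: pd.DataFrame  # samples x clusters latent factors
    seed: int


def simulate_expression_study(
    cluster_sizes: Sequence[int] = (40, 40),
    n_noise_genes: int = 10,
    n_samples: int = 200,
    receptor_couplings: dict[str, tuple[str, float, float]] | None = None,
    condition_log2fc: dict[str, float] | None = None,
    sex_log2fc: dict[str, float] | None = None,
    within_cluster_sigma: float = 0.35,
    loading: float = 1.0,
    base_log2_tpm: float = 5.0,
    tumor_fraction: float = 0.5,
    age_range: tuple[float, float] = (20.0, 80.0),
    count_depth: int | None = 200_000,
    seed: int = 0,
) -> tuple[ExpressionStudy, ExpressionTruth]:
    """Generate an expression study with planted co-expression structure.

    Cluster genes share one latent factor per cluster on the log2 scale
    (within-cluster PCC is set by ``loading`` vs ``within_cluster_sigma``);
    noise genes are independent.  Receptors named in ``receptor_couplings``
    read out ``beta * factor + N(0, sigma)``.  ``condition_log2fc`` adds
    tumor-only shifts (for fold-change gates); ``sex_log2fc`` adds male-only
    shifts.  Counts are a multinomial draw of ``count_depth`` reads per sample.
    """
    if any(s < 2 for s in cluster_sizes):
        raise ValidationError("cluster sizes must be >= 2")
    receptor_couplings = dict(receptor_couplings or {})
    condition_log2fc = dict(condition_log2fc or {})
    sex_log2fc = dict(sex_log2fc or {})
    rng = np.random.default_rng(seed)

    cluster_names = [f"C{i+1}" for i in range(len(cluster_sizes))]
    clusters = {
        name: [f"{name}_g{j:03d}" for j in range(size)]
        for name, size in zip(cluster_names, cluster_sizes)
    }
    for _, (cl, beta, sigma) in receptor_couplings.items():
        if cl not in clusters:
            raise ValidationError(f"receptor coupled to unknown cluster {cl!r}")
        if not (np.isfinite(beta) and np.isfinite(sigma)):
            raise ValidationError("couplings must be finite")
    noise_genes = [f"NOISE_g{j:03d}" for j in range(n_noise_genes)]
    receptors = sorted(receptor_couplings)
    genes = [g for gs in clusters.values() for g in gs] + noise_genes + receptors

    samples = [f"S{j:04d}" for j in range(n_samples)]
    n_tumor = int(round(tumor_fraction * n_samples))
    condition = np.array(["tumor"] * n_tumor + ["control"] * (n_samples - n_tumor))
    sex = np.where(rng.random(n_samples) < 0.5, "male", "female")
    age = rng.uniform(*age_range, size=n_samples).round(1)

    Z = rng.standard_normal((n_samples, len(cluster_names)))
    factors = pd.DataFrame(Z, index=samples, columns=cluster_names)

    log2 = np.empty((len(genes), n_samples))
    row = 0
    for ci, name in enumerate(cluster_names):
        k = len(clusters[name])
        eps = rng.normal(0.0, within_cluster_sigma, size=(k, n_samples))
        log2[row:row + k] = base_log2_tpm + loading * Z[:, ci][None, :] + eps
        row += k
    log2[row:row + n_noise_genes] = base_log2_tpm + rng.standard_normal(
        (n_noise_genes, n_samples))
    row += n_noise_genes
    for r in receptors:
        cl, beta, sigma = receptor_couplings[r]
        ci = cluster_names.index(cl)
        log2[row] = base_log2_tpm + beta * Z[:, ci] + rng.normal(0, sigma, n_samples)
        row += 1

    gene_index = {g: i for i, g in enumerate(genes)}
    is_tumor = condition == "tumor"
    for g, fc in condition_log2fc.items():
        log2[gene_index[g], is_tumor] += fc
    is_male = sex == "male"
    for g, fc in sex_log2fc.items():
        log2[gene_index[g], is_male] += fc

    tpm = pd.DataFrame(np.power(2.0, log2) - 1.0, index=genes, columns=samples)
    tpm[tpm < 0] = 0.0

    counts = None
    if count_depth:
        cmat = np.empty_like(tpm.values)
        for j in range(n_samples):
            p = tpm.values[:, j]
            p = p / p.sum()
            cmat[:, j] = rng.multinomial(count_depth, p)
        counts = pd.DataFrame(cmat.astype(int), index=genes, columns=samples)

    meta = pd.DataFrame(
        {"age": age, "sex": sex, "condition": condition}, index=samples)
    study = ExpressionStudy(tpm=tpm, sample_meta=meta, counts=counts)
    truth = ExpressionTruth(
        clusters=clusters, noise_genes=noise_genes,
        receptor_couplings=receptor_couplings,
        condition_log2fc=condition_log2fc, sex_log2fc=sex_log2fc,
        factors=factors, seed=seed,
    )
    return study, truth


@dataclass
class CohortTruth:
    infection_params: dict
    analyte_params: dict
    cancer_prevalence: float
    ferritin_cancer_log2_shift: float
    seed: int


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


DEFAULT_INFECTION = {
    # age-dependent infection probability: logistic in age with a sex offset
    # (male rates consistently above female, as serology surveys show)
    "HBV": {"intercept": -4.0, "age_slope": 0.03, "male_offset": 0.7, "concordance": 0.95},
    "HCV": {"intercept": -4.5, "age_slope": 0.04, "male_offset": 0.8},
    "HPV16/18": {"intercept": 0.5, "age_slope": -0.05, "male_offset": 0.0},
}

DEFAULT_ANALYTES = {
    # log-normal serum analytes; meanlog at age 40, per-year age slope on the
    # log scale, additive male shift on the log scale
    "ferritin": {"meanlog": np.log(80.0), "sdlog": 0.5, "age_slope": 0.004, "male_shift": 0.8},
    "serum_iron": {"meanlog": np.log(90.0), "sdlog": 0.25, "age_slope": -0.002, "male_shift": 0.15},
    "transferrin_saturation": {"meanlog": np.log(28.0), "sdlog": 0.3, "age_slope": -0.001, "male_shift": 0.12},
    "hemoglobin": {"meanlog": np.log(13.8), "sdlog": 0.07, "age_slope": -0.0005, "male_shift": 0.09},
}


def simulate_cohort(
    n: int = 2000,
    age_range: tuple[float, float] = (20.0, 80.0),
    sex_ratio: float = 0.5,
    infection_params: dict | None = None,
    analyte_params: dict | None = None,
    cancer_prevalence: float = 0.1,
    ferritin_cancer_log2_shift: float = 0.0,
    stray_marker_rate: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a population cohort with serology, analytes and cancer labels.

    Infection is drawn per virus from a logistic model in age with a male
    offset; an HBV infection sets both surface antigen and core antibody
    positive with the given concordance, while uninfected individuals can
    show an isolated stray marker (rate ``stray_marker_rate``) — which the
    both-markers rule correctly calls negative.  Ferritin is shifted by
    ``ferritin_cancer_log2_shift`` log2 units in cancer-labelled individuals.
    """
    if not 0 <= sex_ratio <= 1 or not 0 <= cancer_prevalence <= 1:
        raise ValidationError("probabilities must lie in [0, 1]")
    infection_params = {**DEFAULT_INFECTION, **(infection_params or {})}
    analyte_params = {**DEFAULT_ANALYTES, **(analyte_params or {})}
    rng = np.random.default_rng(seed)

    age = rng.uniform(*age_range, size=n).round(0)
    sex = np.where(rng.random(n) < sex_ratio, "male", "female")
    is_male = sex == "male"

    df = pd.DataFrame({"id": [f"I{i:05d}" for i in range(n)], "age": age, "sex": sex})

    p_hbv = _logistic(infection_params["HBV"]["intercept"]
                      + infection_params["HBV"]["age_slope"] * (age - 40)
                      + infection_params["HBV"]["male_offset"] * is_male)
    hbv_infected = rng.random(n) < p_hbv
    conc = infection_params["HBV"].get("concordance", 1.0)
    both = rng.random(n) < conc
    sa = hbv_infected & (both | (rng.random(n) < 0.5))
    ca = hbv_infected & (both | ~sa)
    stray = (~hbv_infected) & (rng.random(n) < stray_marker_rate)
    stray_is_sa = rng.random(n) < 0.5
    df["hbv_surface_antigen"] = sa | (stray & stray_is_sa)
    df["hbv_core_antibody"] = ca | (stray & ~stray_is_sa)
    df["hbv_infected_truth"] = hbv_infected

    p_hcv = _logistic(infection_params["HCV"]["intercept"]
                      + infection_params["HCV"]["age_slope"] * (age - 40)
                      + infection_params["HCV"]["male_offset"] * is_male)
    df["hcv_rna"] = rng.random(n) < p_hcv

    p_hpv = _logistic(infection_params["HPV16/18"]["intercept"]
                      + infection_params["HPV16/18"]["age_slope"] * (age - 40)
                      + infection_params["HPV16/18"]["male_offset"] * is_male)
    df["hpv16_18"] = rng.random(n) < p_hpv

    df["cancer_label"] = np.where(rng.random(n) < cancer_prevalence, "cancer", "control")

    for name, prm in analyte_params.items():
        mu = (prm["meanlog"] + prm["age_slope"] * (age - 40)
              + prm["male_shift"] * is_male)
        if name == "ferritin" and ferritin_cancer_log2_shift:
            mu = mu + np.log(2.0) * ferritin_cancer_log2_shift * (df["cancer_label"] == "cancer")
        df[name] = np.exp(rng.normal(mu, prm["sdlog"]))

    truth = CohortTruth(
        infection_params=infection_params, analyte_params=analyte_params,
        cancer_prevalence=cancer_prevalence,
        ferritin_cancer_log2_shift=ferritin_cancer_log2_shift, seed=seed,
    )
    return df, truth
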