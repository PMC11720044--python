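"""Gender-disparity series, iron-gene fold changes, permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ador import (
    AgeSeries,
    IronGeneFC,
    ValidationError,
    ferritin_permutation_test,
    fit_ratio_model,
    gender_ratio_series,
    iron_gene_fc,
    serum_gender_compare,
    simulate_cohort,
    simulate_expression_study,
)

GRID = np.arange(20.0, 81.0, 10.0)


class TestGenderRatioSeries:
    def test_equal_rates_give_zero_fd(self):
        m = AgeSeries(GRID, np.full(GRID.size, 12.0))
        f = AgeSeries(GRID, np.full(GRID.size, 12.0))
        np.testing.assert_allclose(gender_ratio_series(m, f).fd, 0.0)

    def test_twofold_male_excess_gives_fd_one(self):
        f = AgeSeries(GRID, 10.0 + GRID)
        m = AgeSeries(GRID, 2 * (10.0 + GRID))
        np.testing.assert_allclose(gender_ratio_series(m, f).fd, 1.0)

    def test_zero_rate_age_excluded(self):
        fv = 10.0 + GRID
        fv[0] = 0.0
        m = AgeSeries(GRID, 10.0 + GRID)
        f = AgeSeries(GRID, fv)
        out = gender_ratio_series(m, f)
        assert 20.0 not in out.ages
        assert out.excluded_ages == (20.0,)

    def test_antisymmetry_under_sex_swap(self):
        rng = np.random.default_rng(0)
        m = AgeSeries(GRID, rng.uniform(5, 50, GRID.size))
        f = AgeSeries(GRID, rng.uniform(5, 50, GRID.size))
        fd_mf = gender_ratio_series(m, f).fd
        fd_fm = gender_ratio_series(f, m).fd
        np.testing.assert_allclose(fd_mf, -fd_fm)

    def test_disjoint_grids_rejected(self):
        m = AgeSeries(GRID, np.ones(GRID.size))
        f = AgeSeries(GRID + 1.0, np.ones(GRID.size))
        with pytest.raises(ValidationError):
            gender_ratio_series(m, f)


class TestIronGeneFC:
    def _study(self, male_shift=0.0, seed=0):
        study, _ = simulate_expression_study(
            cluster_sizes=(5,), n_noise_genes=3, n_samples=300,
            sex_log2fc={"C1_g000": male_shift}, count_depth=None, seed=seed)
        return study

    def test_identical_distributions_give_zero_fc(self):
        study = self._study(male_shift=0.0, seed=1)
        out = iron_gene_fc(study, ["NOISE_g000"], np.arange(20, 81, 20))
        # medians of identically distributed draws differ only by noise
        assert np.abs(out.fc.values).max() < 0.5

    def test_median_arithmetic_with_pseudocount(self):
        # construct exact medians: male 3, female 1 -> log2(4/2) = 1
        samples = [f"s{i}" for i in range(8)]
        tpm = pd.DataFrame([[3, 3, 3, 3, 1, 1, 1, 1]], index=["g"], columns=samples)
        meta = pd.DataFrame({
            "age": 50.0,
            "sex": ["male"] * 4 + ["female"] * 4,
            "condition": "control",
        }, index=samples)
        from ador import ExpressionStudy
        study = ExpressionStudy(tpm=tpm.astype(float), sample_meta=meta)
        out = iron_gene_fc(study, ["g"], [40, 60])
        assert out.fc.iloc[0, 0] == pytest.approx(1.0)

    def test_all_zero_medians_finite(self):
        samples = [f"s{i}" for i in range(6)]
        tpm = pd.DataFrame(0.0, index=["g"], columns=samples)
        meta = pd.DataFrame({"age": 30.0, "sex": ["male"] * 3 + ["female"] * 3,
                             "condition": "control"}, index=samples)
        from ador import ExpressionStudy
        study = ExpressionStudy(tpm=tpm, sample_meta=meta)
        out = iron_gene_fc(study, ["g"], [20, 40])
        assert out.fc.iloc[0, 0] == 0.0

    def test_single_sex_bin_dropped(self):
        samples = [f"s{i}" for i in range(8)]
        tpm = pd.DataFrame(1.0, index=["g"], columns=samples)
        meta = pd.DataFrame({
            # [20,40): males only (dropped); [40,60): both sexes (kept)
            "age": [25.0] * 3 + [45.0, 45.0, 50.0, 50.0, 52.0],
            "sex": ["male"] * 4 + ["female"] * 4,
            "condition": "control",
        }, index=samples)
        from ador import ExpressionStudy
        study = ExpressionStudy(tpm=tpm, sample_meta=meta)
        out = iron_gene_fc(study, ["g"], [20, 40, 60])
        assert out.dropped_bins == (30.0,)
        assert list(out.fc.index) == [50.0]


class TestFitRatioModel:
    def test_planted_iron_gene_selected(self):
        hits = 0
        n_seeds = 20
        ages = np.arange(22.5, 80, 5.0)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            fc_true = rng.normal(0, 0.5, ages.size)
            decoys = rng.normal(0, 0.5, (ages.size, 5))
            table = pd.DataFrame(
                np.column_stack([fc_true, decoys]), index=ages,
                columns=["TFRC"] + [f"D{i}" for i in range(5)])
            fd_vals = 0.8 * fc_true + rng.normal(0, 0.02, ages.size)
            from ador.gender_iron import GenderRatioSeries
            fd = GenderRatioSeries(ages=ages, fd=fd_vals)
            res = fit_ratio_model(fd, IronGeneFC(fc=table))
            if "TFRC" in res.selected_predictors:
                coef = res.coefficients[res.selected_predictors.index("TFRC")]
                hits += abs(coef - 0.8) / 0.8 < 0.10
        assert hits >= 0.9 * n_seeds

    def test_null_input_gives_intercept_only(self):
        ages = np.arange(22.5, 80, 5.0)
        from ador.gender_iron import GenderRatioSeries
        fd = GenderRatioSeries(ages=ages, fd=np.zeros(ages.size))
        table = pd.DataFrame(0.0, index=ages, columns=["g1", "g2"])
        res = fit_ratio_model(fd, IronGeneFC(fc=table))
        assert res.selected_predictors == []

    def test_single_hormone_predictor_variant(self):
        ages = np.arange(22.5, 80, 5.0)
        rng = np.random.default_rng(5)
        e2 = rng.normal(0, 0.4, ages.size)
        from ador.gender_iron import GenderRatioSeries
        fd = GenderRatioSeries(ages=ages, fd=-1.2 * e2 + rng.normal(0, 0.01, ages.size))
        res = fit_ratio_model(fd, pd.DataFrame({"E2_fc": e2}, index=ages))
        assert res.selected_predictors == ["E2_fc"]
        assert res.coefficients[0] == pytest.approx(-1.2, rel=0.1)


class TestPermutationTest:
    def test_exhaustive_enumeration_small_case(self):
        """n=2 cancer {10,10}, m=2 controls {0,0}: no label split strictly
        exceeds the observed cancer mean, so p = 0."""
        values = [10.0, 10.0, 0.0, 0.0]
        labels = ["cancer", "cancer", "control", "control"]
        # enumeration oracle over C(4,2)=6 splits
        exceed = sum(
            np.mean([values[i] for i in comb]) > 10.0
            for comb in itertools.combinations(range(4), 2))
        assert exceed == 0
        res = ferritin_permutation_test(values, labels, iterations=2000, seed=0)
        assert res.p_value == 0.0

    def test_all_identical_values_give_zero_p(self):
        res = ferritin_permutation_test([5.0] * 6, ["cancer"] * 3 + ["control"] * 3,
                                        iterations=500, seed=1)
        assert res.p_value == 0.0  # strict inequality: ties never exceed

    def test_smoothed_variant_never_zero(self):
        res = ferritin_permutation_test([5.0] * 6, ["cancer"] * 3 + ["control"] * 3,
                                        iterations=500, seed=1, smoothed=True)
        assert res.p_value == pytest.approx(1 / 501)

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(4, 0.5, 30)
        labels = ["cancer"] * 10 + ["control"] * 20
        a = ferritin_permutation_test(values, labels, iterations=3000, seed=9)
        b = ferritin_permutation_test(values, labels, iterations=3000, seed=9)
        assert a.p_value == b.p_value

    def test_monte_carlo_matches_enumeration_within_3_sigma(self):
        """For n+m <= 12 the Monte-Carlo estimate converges to the exact
        enumeration value within binomial error."""
        rng = np.random.default_rng(4)
        values = rng.normal(50, 10, 10)
        labels = ["cancer"] * 4 + ["control"] * 6
        observed = values[:4].mean()
        combos = list(itertools.combinations(range(10), 4))
        exact = np.mean([values[list(c)].mean() > observed for c in combos])
        iters = 20_000
        res = ferritin_permutation_test(values, labels, iterations=iters, seed=5)
        tol = 3 * np.sqrt(max(exact * (1 - exact), 1e-12) / iters) + 1e-12
        assert abs(res.p_value - exact) <= tol

    def test_missing_values_dropped_and_counted(self):
        values = [10.0, np.nan, 3.0, 4.0]
        labels = ["cancer", "cancer", "control", "control"]
        res = ferritin_permutation_test(values, labels, iterations=100, seed=0)
        assert res.n_dropped == 1
        assert res.n_cancer == 1

    def test_requires_both_groups(self):
        with pytest.raises(ValidationError):
            ferritin_permutation_test([1.0, 2.0], ["cancer", "cancer"],
                                      iterations=10, seed=0)


class TestSerumGenderCompare:
    def test_identical_samples_not_significant(self):
        vals = np.arange(30.0)
        cohort = pd.DataFrame({
            "age": np.tile(np.linspace(25, 55, 30), 2),
            "sex": ["male"] * 30 + ["female"] * 30,
            "ferritin": np.concatenate([vals, vals]),
        })
        out = serum_gender_compare(cohort, "ferritin", [20, 60])
        assert out["stars"].iloc[0] == "ns"
        assert out["p_value"].iloc[0] == 1.0

    def test_total_separation_highly_significant(self):
        rng = np.random.default_rng(1)
        f = rng.normal(50, 5, 50)
        cohort = pd.DataFrame({
            "age": np.tile(np.linspace(25, 55, 50), 2),
            "sex": ["male"] * 50 + ["female"] * 50,
            "ferritin": np.concatenate([f + 100, f]),
        })
        out = serum_gender_compare(cohort, "ferritin", [20, 60])
        assert out["p_value"].iloc[0] < 1e-4
        assert out["stars"].iloc[0] == "****"

    def test_age_localized_shift_detected_only_below_cutoff(self):
        """Male ferritin shifted +30% below age 60, equal after: significant
        bins appear only below 60 in most seeds."""
        ok = 0
        n_seeds = 10
        bins = np.arange(20, 81, 10)
        for seed in range(n_seeds):
            cohort, _ = simulate_cohort(n=3000, seed=700 + seed)
            shift = np.where((cohort["age"] < 60) & (cohort["sex"] == "male"), 1.3, 1.0)
            cohort = cohort.assign(
                analyte=np.exp(np.log(80) + np.random.default_rng(seed).normal(0, 0.4, len(cohort))) * shift)
            out = serum_gender_compare(cohort, "analyte", bins)
            sig = out[out["p_value"] < 0.05]
            ok += (not sig.empty) and bool((sig["age_hi"] <= 60).all())
        assert ok >= 0.9 * n_seeds

    def test_single_sex_bin_skipped(self):
        cohort = pd.DataFrame({
            "age": [25.0, 27.0, 65.0, 67.0],
            "sex": ["male", "male", "female", "male"],
            "ferritin": [10.0, 12.0, 9.0, 11.0],
        })
        out = serum_gender_compare(cohort, "ferritin", [20, 30, 70])
        assert list(out["age_lo"]) == [30.0]


@settings(max_examples=20, deadline=None)
@given(shift=st.floats(0.1, 5.0))
def test_fc_pseudocount_shrinks_toward_zero_with_baseline(shift):
    """Adding a common baseline to both sexes' medians moves the fold change
    monotonically toward 0 (pseudocount behaviour)."""
    m, f = 8.0, 2.0
    fc0 = np.log2((m + 1) / (f + 1))
    fc1 = np.log2((m + shift + 1) / (f + shift + 1))
    assert abs(fc1) < abs(fc0)
    assert np.sign(fc1) == np.sign(fc0)
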