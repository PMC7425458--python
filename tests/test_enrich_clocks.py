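"""Fisher enrichment with an exhaustive hypergeometric oracle, clock
scoring/acceleration, and score-adjusted mortality models."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from methmort.enrich_clocks import (
    ClockDefinition,
    adjusted_mortality_model,
    age_acceleration,
    apply_clock,
    fisher_enrichment,
    score_cpg_correlations,
)


def _enrich(a, b, c, d):
    """Run fisher_enrichment on an explicit 2x2: a=sig&cat, b=sig&!cat,
    c=nonsig&cat, d=nonsig&!cat."""
    sig = [f"s{i}" for i in range(a + b)]
    nonsig = [f"n{i}" for i in range(c + d)]
    cat = set(sig[:a]) | set(nonsig[:c])
    table = fisher_enrichment(
        sig, sig + nonsig, annot=None, categories={"cat": cat}
    )
    return table.iloc[0]


def tail_p(a, b, c, d):
    """Direct summation oracle: P(X >= a) over tables with fixed margins."""
    N = a + b + c + d
    K = a + c  # category size
    n = a + b  # significant draws
    denom = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(a, min(K, n) + 1)
    ) / denom


class TestFisher:
    def test_worked_hypergeometric_example(self):
        row = _enrich(3, 1, 1, 3)
        assert row["pval"] == pytest.approx(17 / 70, abs=1e-12)

    def test_matches_exhaustive_oracle_small_margins(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 or a + b + c + d == 0:
                continue
            row = _enrich(a, b, c, d)
            assert row["pval"] == pytest.approx(tail_p(a, b, c, d), abs=1e-10), (
                a, b, c, d,
            )

    def test_depletion_direction(self):
        row = _enrich(0, 5, 5, 5)
        assert row["pval"] >= 0.5
        assert row["odds_ratio"] < 1 or row["a"] == 0

    def test_significant_equals_background(self):
        ids = [f"x{i}" for i in range(8)]
        table = fisher_enrichment(
            ids, ids, annot=None, categories={"cat": set(ids[:3])}
        )
        assert table.iloc[0]["pval"] == pytest.approx(1.0)

    def test_empty_significant_set(self):
        ids = [f"x{i}" for i in range(8)]
        table = fisher_enrichment(
            [], ids, annot=None, categories={"cat": set(ids[:3])}
        )
        assert (table["pval"] == 1.0).all()

    def test_annotation_categories_and_fdr(self):
        annot = pd.DataFrame(
            {
                "island_relation": ["Island"] * 6 + ["OpenSea"] * 6,
                "gene_region": ["Body"] * 12,
            },
            index=[f"c{i}" for i in range(12)],
        )
        sig = [f"c{i}" for i in range(4)]  # all Island
        table = fisher_enrichment(sig, list(annot.index), annot)
        island = table.set_index("category").loc["island_relation:Island"]
        assert island["pval"] < 0.1
        assert "fdr_q" in table.columns

    def test_sig_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["a"], ["b"], annot=None, categories={})


class TestClock:
    def test_worked_linear_combination(self):
        clock = ClockDefinition("demo", {"cg1": 1.0, "cg2": -1.0}, intercept=50.0)
        s = pd.Series({"cg1": 0.6, "cg2": 0.2})
        assert apply_clock(s, clock) == pytest.approx(50.4)

    def test_zero_weights_return_intercept(self):
        clock = ClockDefinition("demo", {"cg1": 0.0, "cg2": 0.0}, intercept=37.0)
        s = pd.Series({"cg1": 0.6, "cg2": 0.2})
        assert apply_clock(s, clock) == pytest.approx(37.0)

    def test_mean_imputation_consistency(self):
        clock = ClockDefinition("demo", {"cg1": 2.0, "cg2": 3.0}, intercept=10.0)
        full = pd.DataFrame(
            {"s1": [0.4, 0.6], "s2": [0.4, 0.2]}, index=["cg1", "cg2"]
        )
        missing = full.copy()
        missing.loc["cg2", "s1"] = np.nan  # imputed by the cohort mean (0.2)
        ref = full.copy()
        ref.loc["cg2", "s1"] = 0.2
        np.testing.assert_allclose(
            apply_clock(missing, clock).to_numpy(),
            apply_clock(ref, clock).to_numpy(),
        )

    def test_under_half_observed_flagged(self):
        clock = ClockDefinition("demo", {f"cg{i}": 1.0 for i in range(10)})
        s = pd.Series({"cg0": 0.5, "cg1": 0.5})  # 20% observed
        assert np.isnan(apply_clock(s, clock))

    def test_linearity_of_scoring(self):
        clock = ClockDefinition("demo", {"cg1": 1.5, "cg2": -2.0}, intercept=20.0)
        x = pd.Series({"cg1": 0.3, "cg2": 0.8})
        y = pd.Series({"cg1": 0.6, "cg2": 0.1})
        a, b = 0.3, 0.7
        mix = a * x + b * y
        lhs = apply_clock(mix, clock)
        rhs = (
            a * apply_clock(x, clock)
            + b * apply_clock(y, clock)
            - (a + b - 1) * clock.intercept
        )
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "clock.tsv"
        pd.DataFrame([("INTERCEPT", 50.0), ("cg1", 1.0), ("cg2", -1.0)]).to_csv(
            path, sep="\t", index=False, header=False
        )
        clock = ClockDefinition.from_tsv(path, name="demo")
        assert clock.intercept == 50.0
        assert clock.cpg_weights == {"cg1": 1.0, "cg2": -1.0}


class TestAcceleration:
    def test_difference_mode(self):
        acc = age_acceleration(
            pd.Series([50.4, 60.0]), pd.Series([48.0, 62.0]), mode="difference"
        )
        np.testing.assert_allclose(acc, [2.4, -2.0])

    def test_clock_equals_age_gives_zero_both_modes(self):
        age = pd.Series([50.0, 60.0, 70.0])
        for mode in ("difference", "residual"):
            acc = age_acceleration(age.copy(), age, mode=mode)
            np.testing.assert_allclose(acc, 0.0, atol=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(0)
        age = pd.Series(rng.uniform(50, 80, 40))
        clock = age + pd.Series(rng.normal(0, 3, 40))
        acc = age_acceleration(clock, age, mode="residual")
        assert acc.sum() == pytest.approx(0.0, abs=1e-8)

    def test_constant_age_residual_mode_rejected(self):
        with pytest.raises(ValueError):
            age_acceleration(
                pd.Series([50.0, 51.0]), pd.Series([60.0, 60.0]), mode="residual"
            )


class TestAdjustedMortality:
    def test_independent_score_leaves_cpg_coefficient(self, single_cohort):
        from methmort.survival_ewas import fit_cox_per_cpg

        cpg = single_cohort.beta.index[4]
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(
            {"accel": rng.normal(0, 3, single_cohort.n)},
            index=single_cohort.covariates.index,
        )
        adj = adjusted_mortality_model(single_cohort, cpg, scores, model="basic")
        base = fit_cox_per_cpg(single_cohort, "basic")
        base = base.set_index("cpg_id").loc[cpg]
        assert abs(adj["beta"] - base["beta"]) < 2 * max(adj["se"], base["se"])

    def test_collinear_score_flags_nonconvergence(self, single_cohort):
        cpg = single_cohort.beta.index[0]
        scores = pd.DataFrame(
            {"copy": single_cohort.beta.loc[cpg]},
            index=single_cohort.covariates.index,
        )
        adj = adjusted_mortality_model(single_cohort, cpg, scores, model="basic")
        if adj["converged"]:
            # exact collinearity: if the ridge-stabilized fit reports back,
            # its variance must betray the degeneracy
            from methmort.survival_ewas import fit_cox_per_cpg

            base = fit_cox_per_cpg(single_cohort, "basic").set_index("cpg_id").loc[cpg]
            assert adj["se"] > 5 * base["se"]
        else:
            assert np.isnan(adj["beta"])


class TestScoreCorrelations:
    def test_self_correlation_unity(self, small_cohorts):
        cpg = small_cohorts[0].beta.index[0]
        mat = score_cpg_correlations(small_cohorts, [cpg], [cpg])
        assert mat.iloc[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_anticorrelated_construction(self, small_cohorts):
        import copy

        ds = copy.copy(small_cohorts[0])
        ds.beta = small_cohorts[0].beta.iloc[:2].copy()
        ds.beta.iloc[1] = 1.0 - ds.beta.iloc[0]
        mat = score_cpg_correlations([ds], [ds.beta.index[0]], [ds.beta.index[1]])
        assert mat.iloc[0, 0] == pytest.approx(-1.0, abs=1e-6)

    def test_independent_cpgs_bounded_null_correlation(self, small_cohorts):
        ids = list(small_cohorts[0].beta.index[:10])
        mat = score_cpg_correlations(small_cohorts, ids[:5], ids[5:])
        n_eff = sum(ds.n for ds in small_cohorts)
        # mixture sharing makes CpGs weakly dependent; allow the null bound
        # plus that common-structure floor
        assert np.nanmean(np.abs(mat.to_numpy())) <= 3 / np.sqrt(n_eff) + 0.15

    def test_constant_cpg_flagged(self, small_cohorts):
        import copy

        ds = copy.copy(small_cohorts[0])
        ds.beta = small_cohorts[0].beta.iloc[:2].copy()
        ds.beta.iloc[0] = 0.5
        mat = score_cpg_correlations([ds], [ds.beta.index[0]], [ds.beta.index[1]])
        assert np.isnan(mat.iloc[0, 0])
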