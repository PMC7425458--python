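"""Proportional-hazards engine and the per-CpG screening layer.

The fitter is validated against a closed-form stationary point, against
lifelines (Efron ties) and statsmodels PHReg (Breslow ties) as independent
implementations, and by sampling properties (CI coverage, PH-test
calibration)."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from statsmodels.duration.hazard_regression import PHReg

from methmort.cox import fit_cox, schoenfeld_ph_test
from methmort.survival_ewas import (
    EmptyRiskSetError,
    check_proportional_hazards,
    covariate_design,
    ewas_cohort,
    fit_cox_per_cpg,
    fit_cox_two_step,
    fit_incident_disease,
    hr_per_10pct,
)
from tests.conftest import toy_cox_data

HALF_LN2 = 0.5 * np.log(2.0)


class TestFitter:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_three_subject_closed_form(self, ties):
        # stationary point of the partial likelihood at exp(beta)=1/sqrt(2)
        f = fit_cox(
            np.array([[1.0], [0.0], [1.0]]),
            np.array([1.0, 2.0, 3.0]),
            np.array([1, 1, 1]),
            ties=ties,
        )
        assert f.converged
        assert f.beta[0] == pytest.approx(-HALF_LN2, abs=1e-6)
        assert np.exp(f.beta[0]) == pytest.approx(np.sqrt(0.5), abs=1e-6)

    def test_matches_lifelines_with_ties(self, cox_data):
        X, t, e = cox_data
        mine = fit_cox(X, t, e, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b"]).assign(T=t, E=e)
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(mine.beta, ref.params_.values, atol=1e-6)
        np.testing.assert_allclose(mine.se, ref.standard_errors_.values, atol=1e-6)

    def test_matches_statsmodels_breslow(self, cox_data):
        X, t, e = cox_data
        mine = fit_cox(X, t, e, ties="breslow")
        ref = PHReg(t, X, status=e, ties="breslow").fit()
        np.testing.assert_allclose(mine.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(mine.se, ref.bse, atol=1e-6)

    def test_tie_conventions_agree_on_distinct_times(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        t = rng.exponential(5, 60)  # continuous: no ties
        e = (rng.random(60) < 0.6).astype(int)
        fe = fit_cox(X, t, e, ties="efron")
        fb = fit_cox(X, t, e, ties="breslow")
        np.testing.assert_allclose(fe.beta, fb.beta, atol=1e-9)

    def test_duplicating_subjects_halves_variance(self, cox_data):
        # under Breslow ties the duplicated-sample partial likelihood is an
        # exact multiple of the original, so beta is identical and the
        # information doubles exactly
        X, t, e = cox_data
        f1 = fit_cox(X, t, e, ties="breslow")
        f2 = fit_cox(np.vstack([X, X]), np.r_[t, t], np.r_[e, e], ties="breslow")
        np.testing.assert_allclose(f2.beta, f1.beta, atol=1e-7)
        np.testing.assert_allclose(f2.se, f1.se / np.sqrt(2), rtol=1e-6)
        # Efron's correction perturbs the tied risk sets only slightly
        g2 = fit_cox(np.vstack([X, X]), np.r_[t, t], np.r_[e, e], ties="efron")
        np.testing.assert_allclose(g2.beta, f1.beta, atol=0.01)

    def test_constant_column_flags_nonconverged(self):
        f = fit_cox(np.ones((20, 1)), np.arange(1.0, 21), np.ones(20, int))
        assert not f.converged
        assert np.isnan(f.beta).all()

    def test_too_few_events_flags_nonconverged(self):
        f = fit_cox(np.random.default_rng(0).normal(size=(10, 1)),
                    np.arange(1.0, 11), np.zeros(10, int))
        assert not f.converged

    def test_wald_ci_coverage_and_unbiasedness(self):
        # n=1000 with ~30% events, 500 replicates; the 95% Wald interval
        # must cover the true log-HR at the nominal rate
        rng = np.random.default_rng(42)
        b_true, hits, ests = 0.7, 0, []
        n_rep = 500
        for _ in range(n_rep):
            x = rng.normal(size=1000)
            tt = rng.exponential(1 / (0.05 * np.exp(b_true * x)))
            cc = rng.uniform(0, 12.5, 1000)
            t = np.minimum(tt, cc)
            e = (tt <= cc).astype(int)
            f = fit_cox(x[:, None], t, e)
            ests.append(f.beta[0])
            lo, hi = f.beta[0] - 1.96 * f.se[0], f.beta[0] + 1.96 * f.se[0]
            hits += int(lo <= b_true <= hi)
        cover = hits / n_rep
        assert 0.92 <= cover <= 0.97
        ests = np.asarray(ests)
        assert abs(ests.mean() - b_true) <= 3 * ests.std(ddof=1) / np.sqrt(n_rep)

    def test_hr_reporting_scale(self):
        assert hr_per_10pct(0.0) == 1.0
        assert hr_per_10pct(np.log(2) * 10) == pytest.approx(2.0)


class TestScreen:
    def test_screen_returns_row_per_cpg(self, single_cohort):
        res = fit_cox_per_cpg(single_cohort, "basic", single_cohort.cell_fractions_true)
        assert len(res) == single_cohort.beta.shape[0]
        ok = res[res["converged"]]
        assert (ok["se"] > 0).all()
        assert ((ok["pval"] > 0) & (ok["pval"] <= 1)).all()

    def test_constant_cpg_flagged(self, single_cohort):
        ds = _clone(single_cohort)
        ds.beta = single_cohort.beta.iloc[:3].copy()
        ds.beta.iloc[0] = 0.4
        res = fit_cox_per_cpg(ds, "basic", ds.cell_fractions_true)
        assert not res.iloc[0]["converged"]
        assert res.iloc[1]["converged"]

    def test_missing_covariate_column_raises(self, single_cohort):
        with pytest.raises(KeyError):
            covariate_design(single_cohort.covariates.drop(columns=["bmi"]), "full")

    def test_auto_dispatch_uses_two_step_for_low_death_cohorts(self, single_cohort):
        direct = ewas_cohort(single_cohort, "basic", method="direct")
        auto = ewas_cohort(single_cohort, "basic", method="auto",
                           two_step_threshold=single_cohort.n_events + 1)
        two = fit_cox_two_step(single_cohort, "basic")
        assert not np.allclose(direct["beta"], auto["beta"], equal_nan=True)
        np.testing.assert_allclose(auto["beta"], two["beta"], equal_nan=True)


class TestTwoStep:
    def test_constant_covariates_equal_direct_single_fit(self, single_cohort):
        ds = _clone(single_cohort)
        cov = single_cohort.covariates.copy()
        for c in cov.columns:
            cov[c] = cov[c].iloc[0]
        ds.covariates = cov
        ds.beta = single_cohort.beta.iloc[:5]
        two = fit_cox_two_step(ds, "basic")
        t = ds.time.to_numpy()
        e = ds.event.to_numpy(int)
        for _, row in two.iterrows():
            m = ds.beta.loc[row["cpg_id"]].to_numpy(float)
            obs = np.isfinite(m)
            direct = fit_cox((m[obs] - m[obs].mean())[:, None], t[obs], e[obs])
            assert row["beta"] == pytest.approx(direct.beta[0], abs=1e-8)

    def test_orthogonal_covariates_match_joint_fit(self):
        # methylation orthogonal to the covariate by construction
        rng = np.random.default_rng(8)
        n = 200
        z = rng.normal(size=n)
        m = rng.normal(size=n)
        m = m - z * (z @ m) / (z @ z)
        m = 0.5 + 0.1 * (m - m.mean())  # beta-scale
        tt = rng.exponential(1 / (0.1 * np.exp(2.0 * m)))
        cc = rng.uniform(0, 30, n)
        t, e = np.minimum(tt, cc), (tt <= cc).astype(int)
        joint = fit_cox(np.column_stack([m, z]), t, e)
        A = np.column_stack([np.ones(n), z])
        resid = m - A @ np.linalg.lstsq(A, m, rcond=None)[0]
        two = fit_cox(resid[:, None], t, e)
        # with the nuisance covariate orthogonal to methylation and void of
        # outcome effect, both routes estimate the same quantity; agreement
        # is to within a fraction of the SE (exact equality is a linear-model
        # property, not a partial-likelihood one)
        assert two.beta[0] == pytest.approx(joint.beta[0], abs=0.3 * joint.se[0])

    def test_deterministic_methylation_gives_nonconverged(self, single_cohort):
        ds = _clone(single_cohort)
        ds.beta = single_cohort.beta.iloc[:1].copy()
        # methylation an exact linear function of a covariate
        ds.beta.iloc[0] = 0.3 + 0.01 * ds.covariates["bmi"].to_numpy(float)
        res = fit_cox_two_step(ds, "full")
        assert not res.iloc[0]["converged"]


class TestProportionalHazards:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(21)
        n, rejected, total = 150, 0, 0
        for _ in range(200):
            x = rng.uniform(0, 1, n)
            tt = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))
            cc = rng.uniform(0, 20, n)
            t, e = np.minimum(tt, cc), (tt <= cc).astype(int)
            f = fit_cox(x[:, None], t, e)
            if not f.converged:
                continue
            p = schoenfeld_ph_test(x[:, None], t, e, f)
            if np.isfinite(p):
                total += 1
                rejected += int(p < 0.05)
        assert total > 180
        assert 0.02 <= rejected / total <= 0.10

    def test_crossing_hazards_detected(self):
        rng = np.random.default_rng(22)
        hits, total = 0, 0
        for _ in range(40):
            n = 300
            x = (rng.random(n) < 0.5).astype(float)
            # effect reverses sign at t=4: early harm, late protection,
            # with events balanced on both sides of the switch
            t1 = rng.exponential(1 / (0.08 * np.exp(1.2 * x)), n)
            t2 = 4 + rng.exponential(1 / (0.08 * np.exp(-1.2 * x)), n)
            tt = np.where(t1 < 4, t1, t2)
            t = np.minimum(tt, 25)
            e = (tt <= 25).astype(int)
            f = fit_cox(x[:, None], t, e)
            if not f.converged:
                continue
            total += 1
            hits += int(schoenfeld_ph_test(x[:, None], t, e, f) < 0.05)
        assert hits > total / 2

    def test_two_events_flagged_undefined(self, single_cohort):
        ds = _clone(single_cohort)
        ev = ds.event.copy()
        ev[:] = 0
        ev.iloc[:2] = 1
        ds.event = ev
        p = check_proportional_hazards(ds, ds.beta.index[0], "basic")
        assert np.isnan(p)


class TestIncidentDisease:
    def test_identical_outcome_reproduces_mortality_screen(self, single_cohort):
        ds = _clone(single_cohort)
        ds.beta = single_cohort.beta.iloc[:8]
        cov = ds.covariates.copy()
        cov["chd_history"] = 0  # nobody prevalent
        ds.covariates = cov
        ds.time2, ds.event2 = ds.time, ds.event
        inc = fit_incident_disease(ds, "basic")
        mort = fit_cox_per_cpg(ds, "basic")
        np.testing.assert_allclose(inc["beta"], mort["beta"], equal_nan=True)

    def test_all_prevalent_is_empty_risk_set(self, single_cohort):
        ds = _clone(single_cohort)
        cov = ds.covariates.copy()
        cov["chd_history"] = 1
        ds.covariates = cov
        with pytest.raises(EmptyRiskSetError):
            fit_incident_disease(ds, "basic")


def _clone(ds):
    import copy

    return copy.copy(ds)
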