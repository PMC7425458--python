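"""Per-CpG proportional-hazards screening within one cohort.

Two covariate sets mirror the consortium's harmonized models:

* ``basic``  — age (decade indicator contrasts, youngest decade as
  reference), sex, technical factors (plate/chip/row/column), plus the
  estimated leukocyte fractions (one dropped to break the sum-to-one
  collinearity);
* ``full``   — basic plus education, smoking status, pack-years, BMI,
  recreational physical activity, alcohol, hypertension, diabetes, and
  personal history of cancer and coronary heart disease.

Every CpG gets one row: log-hazard per +1.0 beta-value, SE, two-sided Wald
p, sample/event counts and a convergence flag. Failures never raise — they
flag ``converged=False`` so the QC stage can drop them.

Low-death cohorts use a two-step residual variant (covariates regressed off
each probe by OLS, then a single-predictor hazard fit on the residuals),
selected automatically below a configurable event threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cox import CoxFit, fit_cox, schoenfeld_ph_test

BASIC_COVARIATES = ["age_decade", "sex", "plate", "chip", "row", "column"]
FULL_EXTRA = [
    "education",
    "smoking_status",
    "pack_years",
    "bmi",
    "phys_act",
    "alcohol",
    "hypertension",
    "diabetes",
    "cancer_history",
    "chd_history",
]
#: below this many events a cohort's screen switches to the two-step path
TWO_STEP_EVENT_THRESHOLD = 50

_CATEGORICAL = {"age_decade", "plate", "chip", "row", "column", "education", "smoking_status"}


def hr_per_10pct(loghr_per_unit: float) -> float:
    """Hazard ratio per +10% methylation, the field's reporting scale."""
    return float(np.exp(0.1 * loghr_per_unit))


def covariate_design(
    covariates: pd.DataFrame,
    model: str = "full",
    cell_fractions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Numeric design columns for the chosen covariate set.

    Categorical covariates become indicator contrasts with the first sorted
    level (for age, the youngest observed decade) as reference. Cell
    fractions enter minus the largest-mean compartment.
    """
    if model not in ("basic", "full"):
        raise ValueError(f"model must be 'basic' or 'full', got {model!r}")
    cols = BASIC_COVARIATES + (FULL_EXTRA if model == "full" else [])
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate columns absent: {missing}")
    parts = []
    for c in cols:
        if c in _CATEGORICAL:
            dummies = pd.get_dummies(covariates[c].astype(str), prefix=c, dtype=float)
            dummies = dummies.reindex(sorted(dummies.columns), axis=1).iloc[:, 1:]
            parts.append(dummies)
        else:
            parts.append(covariates[[c]].astype(float))
    X = pd.concat(parts, axis=1)
    if cell_fractions is not None:
        cf = cell_fractions.loc[covariates.index].astype(float)
        drop = cf.mean().idxmax()
        X = pd.concat([X, cf.drop(columns=drop)], axis=1)
    return X


def _result_row(cpg, cohort_id, model, fit: CoxFit, ph_p=np.nan) -> dict:
    return {
        "cpg_id": cpg,
        "cohort_id": cohort_id,
        "model": model,
        "beta": fit.beta[0] if fit.converged else np.nan,
        "se": fit.se[0] if fit.converged else np.nan,
        "pval": fit.pval[0] if fit.converged else np.nan,
        "n": fit.n,
        "events": fit.events,
        "converged": bool(fit.converged),
        "ph_pval": ph_p,
    }


def _screen(
    beta: pd.DataFrame,
    design: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    cohort_id: str,
    model: str,
    ties: str,
) -> pd.DataFrame:
    """Shared per-CpG loop: methylation column prepended to the design."""
    n = design.shape[0]
    Xcov = design.to_numpy(float)
    rows = []
    warm = None
    if int((event == 1).sum()) >= 2 and Xcov.shape[1] > 0:
        base = fit_cox(Xcov, time, event, ties=ties)
        if base.converged:
            warm = np.concatenate([[0.0], base.beta])
    for cpg, meth in beta.iterrows():
        m = meth.to_numpy(float)
        obs = np.isfinite(m)
        X = np.column_stack([m[obs], Xcov[obs]])
        init = warm if obs.all() and warm is not None else None
        fit = fit_cox(X, time[obs], event[obs], ties=ties, init=init)
        rows.append(_result_row(cpg, cohort_id, model, fit))
    return pd.DataFrame(rows)


def fit_cox_per_cpg(
    cohort,
    model: str = "full",
    cell_fractions: pd.DataFrame | None = None,
    ties: str = "efron",
    outcome: tuple[pd.Series, pd.Series] | None = None,
) -> pd.DataFrame:
    """Direct per-CpG Cox screen: methylation + covariates + cell fractions."""
    design = covariate_design(cohort.covariates, model, cell_fractions)
    time, event = (
        (cohort.time, cohort.event) if outcome is None else outcome
    )
    return _screen(
        cohort.beta,
        design,
        time.to_numpy(float),
        event.to_numpy(int),
        cohort.cohort_id,
        model,
        ties,
    )


def fit_cox_two_step(
    cohort,
    model: str = "full",
    cell_fractions: pd.DataFrame | None = None,
    ties: str = "efron",
) -> pd.DataFrame:
    """Two-step residual screen for low-death cohorts.

    Step 1: OLS of each probe's beta values on the covariate set.
    Step 2: single-predictor hazard fit on the step-1 residuals.
    """
    design = covariate_design(cohort.covariates, model, cell_fractions)
    time = cohort.time.to_numpy(float)
    event = cohort.event.to_numpy(int)
    A = np.column_stack([np.ones(design.shape[0]), design.to_numpy(float)])
    rows = []
    for cpg, meth in cohort.beta.iterrows():
        m = meth.to_numpy(float)
        obs = np.isfinite(m)
        coef, *_ = np.linalg.lstsq(A[obs], m[obs], rcond=None)
        resid = m[obs] - A[obs] @ coef
        fit = fit_cox(resid[:, None], time[obs], event[obs], ties=ties)
        rows.append(_result_row(cpg, cohort.cohort_id, model, fit))
    return pd.DataFrame(rows)


def ewas_cohort(
    cohort,
    model: str = "full",
    cell_fractions: pd.DataFrame | None = None,
    method: str = "auto",
    ties: str = "efron",
    two_step_threshold: int = TWO_STEP_EVENT_THRESHOLD,
) -> pd.DataFrame:
    """Dispatch one cohort's screen; ``auto`` mirrors the consortium rule of
    switching low-death cohorts to the two-step path."""
    if method == "auto":
        method = "two_step" if cohort.n_events < two_step_threshold else "direct"
    if method == "direct":
        return fit_cox_per_cpg(cohort, model, cell_fractions, ties)
    if method == "two_step":
        return fit_cox_two_step(cohort, model, cell_fractions, ties)
    raise ValueError(f"unknown method {method!r}")


def check_proportional_hazards(
    cohort,
    cpg_id: str,
    model: str = "full",
    cell_fractions: pd.DataFrame | None = None,
    ties: str = "efron",
) -> float:
    """Scaled-Schoenfeld score test of PH for one CpG's methylation term.

    Returns the two-sided p-value; NaN (flagged undefined) with fewer than
    3 events or a failed fit. Diagnostic only — no automatic exclusion.
    """
    design = covariate_design(cohort.covariates, model, cell_fractions)
    m = cohort.beta.loc[cpg_id].to_numpy(float)
    obs = np.isfinite(m)
    X = np.column_stack([m[obs], design.to_numpy(float)[obs]])
    time = cohort.time.to_numpy(float)[obs]
    event = cohort.event.to_numpy(int)[obs]
    fit = fit_cox(X, time, event, ties=ties)
    if not fit.converged or int(event.sum()) < 3:
        return np.nan
    return schoenfeld_ph_test(X, time, event, fit, column=0)


class EmptyRiskSetError(ValueError):
    """All subjects excluded (e.g. everyone prevalent at baseline)."""


def fit_incident_disease(
    cohort,
    model: str = "full",
    cell_fractions: pd.DataFrame | None = None,
    ties: str = "efron",
    prevalent_col: str = "chd_history",
) -> pd.DataFrame:
    """Screen against the secondary incident-disease outcome.

    Identical contract to :func:`fit_cox_per_cpg` with the alternate
    (time2, event2) outcome; subjects prevalent at baseline are excluded.
    """
    keep = cohort.covariates[prevalent_col].astype(int) == 0
    if not keep.any():
        raise EmptyRiskSetError("all subjects prevalent at baseline")
    sub_cov = cohort.covariates.loc[keep]
    import copy

    sub = copy.copy(cohort)
    sub.covariates = sub_cov
    sub.beta = cohort.beta.loc[:, keep.to_numpy()]
    sub.time = cohort.time[keep]
    sub.event = cohort.event[keep]
    cf = cell_fractions.loc[keep.to_numpy()] if cell_fractions is not None else None
    design = covariate_design(sub_cov, model, cf)
    return _screen(
        sub.beta,
        design,
        cohort.time2[keep].to_numpy(float),
        cohort.event2[keep].to_numpy(int),
        cohort.cohort_id,
        model,
        ties,
    )
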