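"""Fixed-effects pooling of per-cohort EWAS results with multiplicity
control and diagnostics.

Pooling is inverse-variance-weighted fixed effects throughout:
``w_i = 1/se_i^2``, ``beta = sum(w b)/sum(w)``, ``se = sum(w)^(-1/2)``.
Cochran's Q and I^2 are computed from the same weights and used purely as
heterogeneity diagnostics. Genomic inflation lambda is the ratio of the
median association chi-square to its null median, 0.4549364.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def _pool(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, float, float, float]:
    w = 1.0 / ses**2
    bp = float(np.sum(w * betas) / np.sum(w))
    sp = float(np.sum(w) ** -0.5)
    p = float(np.clip(2 * stats.norm.sf(abs(bp / sp)), np.nextafter(0, 1), 1.0))
    q = float(np.sum(w * (betas - bp) ** 2))
    # guard the float fuzz of an exact fit (e.g. a single contributing cohort)
    i2 = 0.0 if q <= 1e-12 else max(0.0, (q - (len(betas) - 1)) / q) * 100.0
    return bp, sp, p, q, i2


def ivw_fixed_effects(
    rows: pd.DataFrame, min_cohorts: int = 3, cohort_order: list[str] | None = None
) -> pd.DataFrame:
    """Pool per-cohort rows (one CpG per group) across all CpGs.

    ``rows`` needs columns cpg_id, cohort_id, beta, se, converged. CpGs with
    fewer than ``min_cohorts`` converged cohorts are omitted; the returned
    frame's ``direction_string`` uses +/-/? in fixed cohort order
    (METAL-style).
    """
    if cohort_order is None:
        cohort_order = sorted(rows["cohort_id"].unique())
    ok = rows[rows["converged"] & np.isfinite(rows["se"]) & (rows["se"] > 0)]
    out = []
    for cpg, grp in ok.groupby("cpg_id", sort=True):
        if grp.shape[0] < min_cohorts:
            continue
        bp, sp, p, q, i2 = _pool(grp["beta"].to_numpy(), grp["se"].to_numpy())
        signs = {c: ("+" if b > 0 else "-") for c, b in zip(grp["cohort_id"], grp["beta"])}
        out.append(
            {
                "cpg_id": cpg,
                "beta_pooled": bp,
                "se_pooled": sp,
                "pval": p,
                "k": grp.shape[0],
                "Q": q,
                "I2": i2,
                "direction_string": "".join(signs.get(c, "?") for c in cohort_order),
            }
        )
    meta = pd.DataFrame(
        out,
        columns=[
            "cpg_id", "beta_pooled", "se_pooled", "pval", "k", "Q", "I2",
            "direction_string",
        ],
    )
    if not meta.empty:
        bonf, fdr = multiplicity(meta["pval"].to_numpy())
        meta["bonferroni_sig"] = bonf
        meta["fdr_sig"] = fdr
    else:
        meta["bonferroni_sig"] = pd.Series(dtype=bool)
        meta["fdr_sig"] = pd.Series(dtype=bool)
    return meta


def genomic_inflation(pvals) -> float:
    """Genomic inflation factor lambda from two-sided p-values."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0,1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def multiplicity(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """(Bonferroni flags, Benjamini-Hochberg FDR flags) at level ``alpha``."""
    p = np.asarray(pvals, dtype=float)
    bonf = p <= alpha / len(p)
    fdr = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    return bonf, fdr


def leave_one_out(
    rows: pd.DataFrame, min_cohorts: int = 3, cohort_order: list[str] | None = None
) -> pd.DataFrame:
    """Re-pool excluding one cohort at a time.

    Returns the concatenation of per-left-out-cohort meta tables with a
    ``left_out`` column; empty (with the same schema) when too few cohorts.
    """
    cohorts = sorted(rows["cohort_id"].unique())
    out = []
    if len(cohorts) >= min_cohorts + 1:
        for left in cohorts:
            sub = ivw_fixed_effects(
                rows[rows["cohort_id"] != left], min_cohorts, cohort_order
            )
            sub.insert(0, "left_out", left)
            out.append(sub)
    if not out:
        empty = ivw_fixed_effects(rows.iloc[0:0], min_cohorts, cohort_order)
        empty.insert(0, "left_out", pd.Series(dtype=object))
        return empty
    return pd.concat(out, ignore_index=True)


def sensitivity_exclusion(
    cohort_stats: pd.DataFrame,
    rows: pd.DataFrame,
    max_death_prop: float = 0.30,
    max_lambda: float = 1.5,
    min_cohorts: int = 3,
    cohort_order: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Re-pool after dropping high-death / inflated cohorts.

    A cohort is dropped when its death proportion >= ``max_death_prop`` or
    its genomic inflation strictly exceeds ``max_lambda`` (a cohort at
    exactly 1.5 is retained). ``cohort_stats`` is indexed by cohort_id with
    columns death_prop and lambda.
    """
    have = set(rows["cohort_id"].unique())
    missing = have - set(cohort_stats.index)
    if missing:
        raise ValueError(f"stats missing for cohorts: {sorted(missing)}")
    drop = [
        c
        for c in sorted(have)
        if cohort_stats.loc[c, "death_prop"] >= max_death_prop
        or cohort_stats.loc[c, "lambda"] > max_lambda
    ]
    if set(drop) == have:
        raise ValueError("sensitivity exclusion removed every cohort")
    kept_rows = rows[~rows["cohort_id"].isin(drop)]
    return ivw_fixed_effects(kept_rows, min_cohorts, cohort_order), drop


def cohort_summary(ewas_by_cohort: pd.DataFrame, cohorts=None) -> pd.DataFrame:
    """Per-cohort death proportion and genomic inflation, the inputs to the
    sensitivity exclusion."""
    out = []
    for cid, grp in ewas_by_cohort.groupby("cohort_id"):
        ok = grp[grp["converged"]]
        lam = genomic_inflation(ok["pval"]) if not ok.empty else np.nan
        with np.errstate(invalid="ignore"):
            ratio = grp["events"].to_numpy(float) / grp["n"].to_numpy(float)
        out.append(
            {
                "cohort_id": cid,
                "death_prop": float(np.nanmedian(ratio)),
                "lambda": lam,
            }
        )
    return pd.DataFrame(out).set_index("cohort_id")
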