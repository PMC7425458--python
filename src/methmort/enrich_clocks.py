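"""Genomic-feature enrichment, generic epigenetic-clock scoring, and
clock/risk-score-adjusted mortality models.

Enrichment is a one-sided (greater) Fisher exact test of significant CpGs
against the post-QC background, per annotation category, BH-FDR corrected
across categories. Clocks are user-supplied linear combinations of CpG
beta values (published coefficient sets are not bundled); age acceleration
defaults to the clock-minus-age difference, with the regression-residual
variant available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cox import fit_cox
from .survival_ewas import _result_row, covariate_design


def fisher_enrichment(
    sig_cpgs, background_cpgs, annot: pd.DataFrame, categories: dict | None = None
) -> pd.DataFrame:
    """One-sided enrichment of significant CpGs over the background.

    ``categories`` maps category name -> CpG id set; when omitted the
    island-relation and gene-region annotation columns supply them. An
    empty significant set yields p = 1 everywhere.
    """
    sig = set(sig_cpgs)
    bg = set(background_cpgs)
    if not sig <= bg:
        raise ValueError("significant set must be a subset of the background")
    if categories is None:
        categories = {}
        for col in ("island_relation", "gene_region"):
            for level in sorted(annot[col].astype(str).unique()):
                ids = set(annot.index[annot[col].astype(str) == level]) & bg
                categories[f"{col}:{level}"] = ids
    rows = []
    N, n_sig = len(bg), len(sig)
    for name, ids in categories.items():
        ids = set(ids) & bg
        a = len(sig & ids)
        b = n_sig - a
        c = len(ids) - a
        d = N - n_sig - c
        # hypergeometric upper tail P(X >= a)
        p = float(stats.hypergeom.sf(a - 1, N, len(ids), n_sig)) if n_sig else 1.0
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {"category": name, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": odds, "pval": min(p, 1.0)}
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr_q"] = multipletests(table["pval"], method="fdr_bh")[1]
    return table


@dataclass
class ClockDefinition:
    """A linear epigenetic clock: intercept + sum(weight * beta)."""

    name: str
    cpg_weights: dict[str, float]
    intercept: float = 0.0
    units: str = "years"

    def __post_init__(self):
        if not self.cpg_weights:
            raise ValueError("clock needs at least one weight")
        if not np.all(np.isfinite(list(self.cpg_weights.values()))):
            raise ValueError("non-finite clock weight")

    @classmethod
    def from_tsv(cls, path, name=None, units="years"):
        df = pd.read_csv(path, sep="\t", header=None, names=["cpg_id", "weight"])
        icpt = 0.0
        mask = df["cpg_id"] == "INTERCEPT"
        if mask.any():
            icpt = float(df.loc[mask, "weight"].iloc[0])
            df = df[~mask]
        return cls(name or str(path), dict(zip(df["cpg_id"], df["weight"])), icpt, units)


def apply_clock(
    beta: pd.DataFrame | pd.Series, clock: ClockDefinition, min_observed: float = 0.5
):
    """Clock score per sample; missing clock CpGs imputed by the cohort mean.

    Samples (or the whole call) with under ``min_observed`` of the clock's
    CpGs present come back NaN (flagged missing).
    """
    if isinstance(beta, pd.Series):
        return float(apply_clock(beta.to_frame(), clock, min_observed).iloc[0])
    ids = list(clock.cpg_weights)
    present = [c for c in ids if c in beta.index]
    if len(present) / len(ids) < min_observed:
        return pd.Series(np.nan, index=beta.columns, name=clock.name)
    sub = beta.reindex(ids)
    means = sub.mean(axis=1)
    filled = sub.apply(lambda col: col.fillna(means))
    w = pd.Series(clock.cpg_weights)
    score = clock.intercept + filled.mul(w, axis=0).sum(axis=0, skipna=False)
    # a CpG absent everywhere has NaN mean: score undefined
    frac_obs = sub.notna().sum(axis=0) / len(ids)
    score[frac_obs < min_observed] = np.nan
    return score.rename(clock.name)


def age_acceleration(
    clock_values: pd.Series, chron_age: pd.Series, mode: str = "difference"
) -> pd.Series:
    """Clock age acceleration: plain discrepancy or age-regression residual."""
    if mode == "difference":
        return (clock_values - chron_age).rename("acceleration")
    if mode == "residual":
        age = chron_age.to_numpy(float)
        if np.std(age) < 1e-12:
            raise ValueError("residual mode undefined with constant age")
        A = np.column_stack([np.ones(len(age)), age])
        coef, *_ = np.linalg.lstsq(A, clock_values.to_numpy(float), rcond=None)
        return pd.Series(
            clock_values.to_numpy(float) - A @ coef,
            index=clock_values.index,
            name="acceleration",
        )
    raise ValueError(f"unknown mode {mode!r}")


def adjusted_mortality_model(
    cohort,
    cpg_id: str,
    adjusters: pd.DataFrame,
    model: str = "full",
    cell_fractions: pd.DataFrame | None = None,
) -> dict:
    """Fully-adjusted hazard fit for one CpG with aging/risk scores appended.

    ``adjusters`` holds one column per score (acceleration measures,
    mortality risk score), indexed by sample.
    """
    design = covariate_design(cohort.covariates, model, cell_fractions)
    adj = adjusters.loc[cohort.covariates.index].astype(float)
    m = cohort.beta.loc[cpg_id].to_numpy(float)
    X = np.column_stack([m, adj.to_numpy(), design.to_numpy(float)])
    obs = np.all(np.isfinite(X), axis=1)
    fit = fit_cox(X[obs], cohort.time.to_numpy(float)[obs], cohort.event.to_numpy(int)[obs])
    return _result_row(cpg_id, cohort.cohort_id, f"{model}+scores", fit)


def score_cpg_correlations(
    cohorts, score_cpgs, target_cpgs
) -> pd.DataFrame:
    """Pooled Pearson correlations between risk-score CpGs and target CpGs.

    Within-cohort correlations are Fisher-z transformed and pooled by
    inverse variance (n - 3); constant CpGs give NaN entries.
    """
    score_cpgs, target_cpgs = list(score_cpgs), list(target_cpgs)
    zsum = np.zeros((len(score_cpgs), len(target_cpgs)))
    wsum = np.zeros_like(zsum)
    for ds in cohorts:
        B = ds.beta
        for i, sc in enumerate(score_cpgs):
            for j, tc in enumerate(target_cpgs):
                if sc not in B.index or tc not in B.index:
                    continue
                x = B.loc[sc].to_numpy(float)
                y = B.loc[tc].to_numpy(float)
                obs = np.isfinite(x) & np.isfinite(y)
                if obs.sum() < 4 or np.std(x[obs]) < 1e-12 or np.std(y[obs]) < 1e-12:
                    continue
                r = float(np.corrcoef(x[obs], y[obs])[0, 1])
                r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
                w = obs.sum() - 3
                zsum[i, j] += w * np.arctanh(r)
                wsum[i, j] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.tanh(zsum / wsum)
    pooled[wsum == 0] = np.nan
    return pd.DataFrame(pooled, index=score_cpgs, columns=target_cpgs)
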