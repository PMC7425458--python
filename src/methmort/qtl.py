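"""meQTL and eQTM association scans with cis/trans classification.

meQTL: per SNP-CpG pair, a linear model adjusted for age, sex, BMI and
white-blood-cell proportions. By default the SNP dosage is the dependent
variable and methylation the predictor (an unusual orientation that some
consortium analysis plans specify; ``direction="meth_on_snp"`` gives the
conventional regression of methylation on dosage). Only pairs below the
retention p-value survive (default 1e-4); genome-wide significance is
flagged at 1e-14.

eQTM: per CpG-expression pair on the same chromosome, expression regressed
on methylation with covariates and a random intercept for RNA amplification
batch. Distance is measured from the CpG position to the nearest edge of
the gene interval (0 inside); pairs within 500,000 bp are cis, beyond are
trans (boundary inclusive of cis).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

CIS_BP = 500_000

GENO_QC_DEFAULTS = {"min_call_rate": 0.98, "min_hwe_p": 5e-6, "min_maf": 0.01}


def genotype_qc(meta: pd.DataFrame, **thresholds) -> tuple[list[str], dict]:
    """Pre-filter SNPs on call rate, Hardy-Weinberg p and MAF.

    ``meta`` is indexed by snp_id with columns call_rate, hwe_p, maf.
    """
    th = {**GENO_QC_DEFAULTS, **thresholds}
    counts = {"call_rate": 0, "hwe": 0, "maf": 0, "kept": 0}
    kept = []
    for snp, row in meta.iterrows():
        if row["call_rate"] < th["min_call_rate"]:
            counts["call_rate"] += 1
        elif row["hwe_p"] < th["min_hwe_p"]:
            counts["hwe"] += 1
        elif row["maf"] < th["min_maf"]:
            counts["maf"] += 1
        else:
            kept.append(snp)
    counts["kept"] = len(kept)
    return kept, counts


def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of Y on [1, C] (Frisch-Waugh projection)."""
    A = np.column_stack([np.ones(Y.shape[0]), C])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return Y - A @ coef


def classify_distance(
    cpg_pos: int, start: int, end: int, cis_bp: int = CIS_BP
) -> tuple[int, str]:
    """(distance to interval, cis/trans) for same-chromosome pairs."""
    if start > end:
        start, end = end, start
    if start <= cpg_pos <= end:
        d = 0
    else:
        d = int(min(abs(cpg_pos - start), abs(cpg_pos - end)))
    return d, ("cis" if d <= cis_bp else "trans")


def meqtl_scan(
    beta: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    retain_p: float = 1e-4,
    sig_p: float = 1e-14,
    direction: str = "snp_on_meth",
) -> pd.DataFrame:
    """All-pairs SNP x CpG linear scan with covariate adjustment.

    ``beta`` is CpG x sample, ``genotypes`` SNP dosage x sample (values in
    [0,2]), ``covariates`` numeric sample x covariate. Constant CpGs or
    dosages are skipped (tallied in the ``n_skipped`` attribute of the
    result). Implemented by residualizing both blocks on the covariates,
    which is exactly the per-pair OLS fit.
    """
    samples = beta.columns.intersection(genotypes.columns)
    if len(samples) == 0:
        raise ValueError("no shared samples")
    if direction not in ("snp_on_meth", "meth_on_snp"):
        raise ValueError("direction must be 'snp_on_meth' or 'meth_on_snp'")
    M = beta[samples].to_numpy(float).T  # n x n_cpg
    G = genotypes[samples].to_numpy(float).T  # n x n_snp
    C = covariates.loc[samples].to_numpy(float)
    n, q = C.shape[0], C.shape[1] + 1

    keep_m = M.std(axis=0) > 1e-12
    keep_g = G.std(axis=0) > 1e-12
    n_skipped = int((~keep_m).sum() * G.shape[1] + keep_m.sum() * (~keep_g).sum())
    Rm = _residualize(M[:, keep_m], C)
    Rg = _residualize(G[:, keep_g], C)

    sm_ = np.sqrt((Rm**2).sum(axis=0))
    sg_ = np.sqrt((Rg**2).sum(axis=0))
    corr = (Rm.T @ Rg) / np.outer(sm_, sg_)  # cpg x snp
    corr = np.clip(corr, -1 + 1e-15, 1 - 1e-15)
    df = n - q - 1
    tstat = corr * np.sqrt(df / (1 - corr**2))
    pval = 2 * stats.t.sf(np.abs(tstat), df)

    if direction == "snp_on_meth":  # SNP dependent, methylation independent
        slope = corr * (sg_[None, :] / sm_[:, None])
        se = slope / np.where(tstat == 0, np.nan, tstat)
    else:  # methylation dependent
        slope = corr * (sm_[:, None] / sg_[None, :])
        se = slope / np.where(tstat == 0, np.nan, tstat)

    cpgs = beta.index[keep_m]
    snps = genotypes.index[keep_g]
    ci, si = np.where(pval < retain_p)
    out = pd.DataFrame(
        {
            "cpg_id": cpgs[ci],
            "partner_id": snps[si],
            "beta": slope[ci, si],
            "se": np.abs(se[ci, si]),
            "pval": pval[ci, si],
            "significant": pval[ci, si] < sig_p,
        }
    )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["n_tested"] = int(keep_m.sum() * keep_g.sum())
    return out


def eqtm_scan(
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    batch: pd.Series,
    cpg_annot: pd.DataFrame,
    gene_annot: pd.DataFrame,
    cis_bp: int = CIS_BP,
) -> pd.DataFrame:
    """Per-pair mixed-effects eQTM scan, same-chromosome pairs only.

    ``expression`` is probe x sample (log2, quantile-normalized upstream);
    ``gene_annot`` indexed by probe with chrom/start/end; ``cpg_annot``
    indexed by cpg_id with chrom/pos. With a single batch level the model
    degrades to a fixed intercept (with a warning).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api  # noqa: F401  (MixedLM route)

    samples = beta.columns.intersection(expression.columns)
    bvec = batch.loc[samples]
    single_batch = bvec.nunique() < 2
    if single_batch:
        warnings.warn("single batch level: fitting fixed intercept only")
    C = covariates.loc[samples].to_numpy(float)
    rows = []
    for cpg in beta.index:
        if cpg not in cpg_annot.index:
            continue
        cchrom, cpos = cpg_annot.loc[cpg, "chrom"], int(cpg_annot.loc[cpg, "pos"])
        m = beta.loc[cpg, samples].to_numpy(float)
        for probe in expression.index:
            g = gene_annot.loc[probe]
            if str(g["chrom"]) != str(cchrom):
                continue  # cross-chromosome pairs are out of contract
            y = expression.loc[probe, samples].to_numpy(float)
            X = sm.add_constant(np.column_stack([m, C]))
            if single_batch:
                res = sm.OLS(y, X).fit()
                coef, se, p = res.params[1], res.bse[1], res.pvalues[1]
            else:
                md = sm.MixedLM(y, X, groups=bvec.to_numpy())
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = md.fit(reml=True, method="lbfgs")
                coef, se, p = res.params[1], res.bse[1], res.pvalues[1]
            d, ct = classify_distance(cpos, int(g["start"]), int(g["end"]), cis_bp)
            rows.append(
                {
                    "cpg_id": cpg,
                    "partner_id": probe,
                    "beta": float(coef),
                    "se": float(se),
                    "pval": float(p),
                    "distance": d,
                    "cis_trans": ct,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cpg_id", "partner_id", "beta", "se", "pval", "distance", "cis_trans"],
    )
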