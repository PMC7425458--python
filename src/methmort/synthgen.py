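"""Multi-cohort synthetic data with the structure a blood-methylation
mortality EWAS assumes.

The generator emulates a consortium of population cohorts assayed on a
450K-style array:

* per-cohort beta matrices (CpG x sample, values in [0,1]) built as
  sample-specific mixtures of leukocyte reference profiles plus logit-scale
  noise — so reference-based deconvolution is well posed on the same data;
* harmonized covariates (age decades, sex, lifestyle, comorbidities,
  plate/chip/row/column technical factors);
* right-censored survival under an exponential proportional-hazards model
  whose linear predictor combines configurable causal CpG effects and
  covariate effects, with administrative plus uniform-dropout censoring;
* a secondary incident-disease outcome with the same machinery;
* SNP->CpG / SNP->outcome GWAS summary statistics for two-sample MR.

All randomness flows from explicit integer seeds; cohort c uses its own
``default_rng(seed + c)`` stream so cohorts are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CELL_TYPES",
    "SimConfig",
    "CohortDataset",
    "GwasSummary",
    "ReferenceMatrix",
    "generate_reference_matrix",
    "generate_cohorts",
    "generate_annotation",
    "generate_mr_summaries",
    "write_cohort_tsvs",
    "write_gwas_tsv",
]

#: leukocyte compartments resolved by the 450K whole-blood reference
CELL_TYPES = ("CD4T", "CD8T_naive", "CD8T_mem_eff", "NK", "Bcell", "Mono", "Gran")

#: typical adult whole-blood mean fractions (granulocytes dominate)
_MEAN_FRACTIONS = np.array([0.15, 0.05, 0.07, 0.06, 0.05, 0.07, 0.55])

LYMPHOID_TYPES = ("CD4T", "CD8T_naive", "CD8T_mem_eff", "NK", "Bcell")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def cpg_name(i: int) -> str:
    return f"cg{i:08d}"


# --------------------------------------------------------------------------
# reference matrix


@dataclass
class ReferenceMatrix:
    """Cell-type x CpG mean methylation profiles."""

    cell_types: list[str]
    cpg_ids: list[str]
    profiles: np.ndarray  # (n_types, n_cpgs) in [0,1]
    discriminating: list[str]
    conditioning_warning: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=self.cell_types, columns=self.cpg_ids)

    def discriminating_index(self) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cpg_ids)}
        return np.array([pos[c] for c in self.discriminating])


def generate_reference_matrix(
    cell_types=CELL_TYPES, n_cpgs: int = 500, seed: int = 0
) -> ReferenceMatrix:
    """Reference profiles with a designated strongly discriminating subset.

    Each cell type receives marker CpGs at which it sits near 0.9 while all
    other types sit near 0.1 (pairwise separation >= 0.3 on the subset, so
    the deconvolution design is full column rank). Duplicate cell-type names
    request identical profiles; that rank deficiency sets
    ``conditioning_warning`` instead of raising.
    """
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise ConfigurationError("need at least 2 cell types")
    if n_cpgs <= 0:
        raise ConfigurationError("n_cpgs must be positive")
    rng = np.random.default_rng(seed)
    uniq = list(dict.fromkeys(cell_types))
    K, Ku = len(cell_types), len(uniq)
    cpg_ids = [cpg_name(i) for i in range(n_cpgs)]

    n_markers = max(1, min(15, n_cpgs // (2 * Ku)))
    base = 0.05 + 0.9 * rng.beta(2.0, 2.0, size=n_cpgs)
    prof_u = np.clip(base[None, :] + rng.normal(0, 0.03, size=(Ku, n_cpgs)), 0.02, 0.98)
    disc: list[str] = []
    for k in range(Ku):
        cols = range(k * n_markers, (k + 1) * n_markers)
        for j in cols:
            if j >= n_cpgs:
                break
            prof_u[:, j] = 0.1
            prof_u[k, j] = 0.9
            disc.append(cpg_ids[j])
    profiles = np.vstack([prof_u[uniq.index(ct)] for ct in cell_types])

    dj = [cpg_ids.index(c) for c in disc]
    warn = Ku < K
    if dj:
        sub = profiles[:, dj]
        if np.linalg.matrix_rank(sub.T, tol=1e-8) < K:
            warn = True
        for a in range(K):
            for b in range(a + 1, K):
                if np.max(np.abs(sub[a] - sub[b])) < 0.3:
                    warn = True
    return ReferenceMatrix(cell_types, cpg_ids, profiles, disc, warn)


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic consortium.

    Defaults describe a realistic cohort: ~250 subjects, baseline death
    hazard 0.02/year at the covariate reference (age 65), administrative
    censoring at 15 years plus uniform dropout — giving roughly 20% deaths
    over a ~10-year mean follow-up, the regime the analysis targets.
    """

    n_cohorts: int = 4
    n_subjects_per_cohort: int = 250
    n_cpgs: int = 500
    causal_cpg_ids: tuple[str, ...] = ()
    causal_loghr_per_unit_beta: float = 0.5
    #: logit-scale separation of a latent biallelic meQTL group at causal
    #: CpGs; 0 keeps causal CpGs unimodal, ~3.5 makes them bimodal
    #: (levels near 0.15/0.85, cross-sample sd ~0.35)
    causal_bimodal_delta: float = 0.0
    baseline_hazard_scale: float = 0.02  # events per year
    admin_censor_years: float = 15.0
    dropout_max_years: float = 30.0
    covariate_effect_sizes: dict = field(
        default_factory=lambda: {"age_years": 0.075, "sex": 0.4}
    )
    cell_noise_sd: float = 0.3  # logit-scale
    missing_rate: float = 0.02
    chd_baseline_hazard_scale: float = 0.015
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cohorts", "n_subjects_per_cohort", "n_cpgs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0,1)")
        if self.admin_censor_years < 0 or self.baseline_hazard_scale <= 0:
            raise ConfigurationError("hazard/censoring parameters out of range")


@dataclass
class CohortDataset:
    """One cohort: methylation, covariates, outcomes and simulation truth."""

    cohort_id: str
    beta: pd.DataFrame  # CpG x sample, NaN where masked
    covariates: pd.DataFrame  # sample rows
    time: pd.Series  # years to death or censoring
    event: pd.Series  # 1 = death observed
    time2: pd.Series  # secondary outcome (incident disease)
    event2: pd.Series
    cell_fractions_true: pd.DataFrame  # sample x cell type
    truth: pd.Series  # per-CpG true log-HR per unit beta

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


_EFFECT_CENTER = {"age_years": 65.0, "bmi": 27.0}


def _effect_column(cov: pd.DataFrame, key: str) -> np.ndarray:
    if key in ("smoking_current", "smoking_former"):
        return (cov["smoking_status"] == key.split("_")[1]).to_numpy(float)
    if key not in cov.columns:
        raise ConfigurationError(f"unknown covariate effect {key!r}")
    x = cov[key].to_numpy(float)
    return x - _EFFECT_CENTER.get(key, 0.0)


def _simulate_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = rng.uniform(50, 89, n)
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.45, 0.35, 0.20])
    pack_years = np.where(smoking == "never", 0.0, rng.gamma(2.0, 10.0, n))
    cov = pd.DataFrame(
        {
            "age_years": age,
            "age_decade": pd.Categorical((age // 10).astype(int).astype(str) + "0s"),
            "sex": rng.integers(0, 2, n),
            "education": rng.choice(["low", "mid", "high"], size=n, p=[0.3, 0.4, 0.3]),
            "smoking_status": smoking,
            "pack_years": pack_years,
            "bmi": rng.normal(27, 4, n),
            "phys_act": rng.gamma(2.0, 2.0, n),  # hours/week
            "alcohol": rng.gamma(1.5, 3.0, n),  # drinks/week
            "hypertension": rng.binomial(1, 0.35, n),
            "diabetes": rng.binomial(1, 0.12, n),
            "cancer_history": rng.binomial(1, 0.10, n),
            "chd_history": rng.binomial(1, 0.12, n),
            "plate": rng.choice(["P1", "P2"], n),
            "chip": rng.choice(["C1", "C2"], n),
            "row": rng.choice(["R1", "R2", "R3", "R4"], n),
            "column": rng.choice(["L1", "L2"], n),
        }
    )
    return cov


def generate_cohorts(
    config: SimConfig, ref: ReferenceMatrix | None = None
) -> list[CohortDataset]:
    """Simulate ``config.n_cohorts`` independent cohorts.

    Deterministic given ``config.seed``; cohort c draws everything from
    ``default_rng(seed + c)``.
    """
    if ref is None:
        ref = generate_reference_matrix(n_cpgs=config.n_cpgs, seed=config.seed)
    if len(ref.cpg_ids) != config.n_cpgs:
        raise ConfigurationError("reference matrix size does not match n_cpgs")
    cpg_ids = ref.cpg_ids
    missing = set(config.causal_cpg_ids) - set(cpg_ids)
    if missing:
        raise ConfigurationError(f"causal CpGs not among generated CpGs: {sorted(missing)}")
    causal_idx = np.array([cpg_ids.index(c) for c in config.causal_cpg_ids], dtype=int)
    loghr = config.causal_loghr_per_unit_beta
    if np.isscalar(loghr):
        loghr_vec = np.full(len(causal_idx), float(loghr))
    else:
        loghr_vec = np.array([loghr[c] for c in config.causal_cpg_ids], dtype=float)
    truth = pd.Series(0.0, index=cpg_ids, name="true_loghr")
    truth.iloc[causal_idx] = loghr_vec

    cohorts = []
    for c in range(config.n_cohorts):
        rng = np.random.default_rng(config.seed + c)
        n = config.n_subjects_per_cohort
        cid = f"COH{c + 1:02d}"
        samples = [f"{cid}_S{i:04d}" for i in range(n)]

        cov = _simulate_covariates(rng, n)
        cov.index = samples

        W = rng.dirichlet(_MEAN_FRACTIONS * 60.0, size=n)  # n x K
        frac = pd.DataFrame(W, index=samples, columns=list(ref.cell_types))

        mix = W @ ref.profiles  # n x m, exact mixture of reference means
        x = logit(np.clip(mix, 1e-3, 1 - 1e-3))
        if config.cell_noise_sd > 0:
            x = x + rng.normal(0.0, config.cell_noise_sd, size=x.shape)
        if config.causal_bimodal_delta > 0 and len(causal_idx):
            geno = rng.binomial(1, 0.5, size=(n, len(causal_idx)))
            x[:, causal_idx] += (geno - 0.5) * config.causal_bimodal_delta
        beta = expit(x)  # n x m in (0,1)

        lp = np.zeros(n)
        if len(causal_idx):
            lp += beta[:, causal_idx] @ loghr_vec
        for key, eff in config.covariate_effect_sizes.items():
            lp += eff * _effect_column(cov, key)

        rate = config.baseline_hazard_scale * np.exp(lp)
        t_death = rng.exponential(1.0 / rate)
        censor = np.minimum(
            config.admin_censor_years, rng.uniform(0.0, config.dropout_max_years, n)
        )
        time = np.minimum(t_death, censor)
        event = (t_death <= censor) & (censor > 0)

        rate2 = config.chd_baseline_hazard_scale * np.exp(lp)
        t_chd = rng.exponential(1.0 / rate2)
        time2 = np.minimum(t_chd, censor)
        event2 = (t_chd <= censor) & (censor > 0)

        if config.missing_rate > 0:
            mask = rng.random(beta.shape) < config.missing_rate
            beta = np.where(mask, np.nan, beta)

        cohorts.append(
            CohortDataset(
                cohort_id=cid,
                beta=pd.DataFrame(beta.T, index=cpg_ids, columns=samples),
                covariates=cov,
                time=pd.Series(time, index=samples, name="time"),
                event=pd.Series(event.astype(int), index=samples, name="event"),
                time2=pd.Series(time2, index=samples, name="time2"),
                event2=pd.Series(event2.astype(int), index=samples, name="event2"),
                cell_fractions_true=frac,
                truth=truth.copy(),
            )
        )
    return cohorts


# --------------------------------------------------------------------------
# probe annotation manifest

_ISLAND = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
_ISLAND_P = [0.30, 0.12, 0.12, 0.05, 0.05, 0.36]
_REGION = ["Body", "1stExon", "3'UTR", "5'UTR", "TSS200", "TSS1500", "Intergenic"]
_REGION_P = [0.33, 0.04, 0.04, 0.07, 0.12, 0.15, 0.25]

DEFAULT_FLAG_RATES = {
    "is_control": 0.01,
    "is_noncpg": 0.01,
    "is_crossreactive": 0.02,
    "snp_within_10bp": 0.02,
    "allosomal": 0.03,
}


def generate_annotation(
    cpg_ids, seed: int = 0, flag_rates: dict | None = None
) -> pd.DataFrame:
    """450K-manifest-style annotation for simulated CpGs.

    ``flag_rates`` controls the fraction of probes carrying each exclusion
    flag (pass an all-zero dict for a clean manifest).
    """
    rates = dict(DEFAULT_FLAG_RATES)
    if flag_rates is not None:
        rates.update(flag_rates)
    rng = np.random.default_rng(seed)
    m = len(cpg_ids)
    chrom = rng.integers(1, 23, m).astype(str)
    allo = rng.random(m) < rates["allosomal"]
    chrom[allo] = rng.choice(["X", "Y"], size=int(allo.sum()), p=[0.8, 0.2])
    region = rng.choice(_REGION, size=m, p=_REGION_P)
    gene = np.where(
        region == "Intergenic", "", np.array([f"GENE{i % 97:03d}" for i in range(m)])
    )
    return pd.DataFrame(
        {
            "cpg_id": list(cpg_ids),
            "chrom": chrom,
            "pos": rng.integers(1, 2_000_000_00, m),
            "gene_name": gene,
            "island_relation": rng.choice(_ISLAND, size=m, p=_ISLAND_P),
            "gene_region": region,
            "is_control": rng.random(m) < rates["is_control"],
            "is_noncpg": rng.random(m) < rates["is_noncpg"],
            "is_crossreactive": rng.random(m) < rates["is_crossreactive"],
            "snp_within_10bp": rng.random(m) < rates["snp_within_10bp"],
        }
    ).set_index("cpg_id")


# --------------------------------------------------------------------------
# MR summary statistics


@dataclass
class GwasSummary:
    """One SNP association row of a GWAS summary-statistics file."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self):
        if self.se <= 0:
            raise ConfigurationError("se must be > 0")
        if not 0 < self.eaf < 1:
            raise ConfigurationError("eaf must be in (0,1)")
        for a in (self.effect_allele, self.other_allele):
            if a not in "ACGT":
                raise ConfigurationError(f"bad allele {a!r}")


_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"), ("G", "A"), ("G", "T"),
    ("T", "C"), ("T", "G"), ("A", "T"), ("C", "G"),  # last two palindromic
]


def generate_mr_summaries(
    n_snps: int,
    true_effect: float,
    pleiotropy_frac: float,
    pleiotropy_mean: float,
    seed: int,
    pleiotropy_sd: float = 0.05,
    exposure_se: float = 0.005,
    outcome_se: float = 0.02,
    palindromic_frac: float = 0.0,
    n_exposure: int = 5000,
    n_outcome: int = 60000,
) -> tuple[list[GwasSummary], list[GwasSummary]]:
    """SNP->exposure and SNP->outcome summary statistics for two-sample MR.

    Outcome effects follow ``by = true_effect * bx + alpha + noise`` where
    ``alpha`` is zero for valid instruments and Normal(pleiotropy_mean,
    pleiotropy_sd) for the pleiotropic fraction (InSIDE holds: alpha is
    independent of instrument strength).
    """
    if n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    if not 0 <= pleiotropy_frac <= 1:
        raise ConfigurationError("pleiotropy_frac must be in [0,1]")
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(0.05, 0.30, n_snps)
    n_pal = int(round(palindromic_frac * n_snps))
    pair_idx = np.concatenate(
        [
            rng.integers(0, 8, n_snps - n_pal),
            rng.integers(8, 10, n_pal),
        ]
    )
    rng.shuffle(pair_idx)
    n_pleio = int(round(pleiotropy_frac * n_snps))
    is_pleio = np.zeros(n_snps, bool)
    is_pleio[rng.choice(n_snps, n_pleio, replace=False)] = True
    alpha = np.where(is_pleio, rng.normal(pleiotropy_mean, pleiotropy_sd, n_snps), 0.0)

    bx_obs = bx_true + rng.normal(0, exposure_se, n_snps)
    by_obs = true_effect * bx_true + alpha + rng.normal(0, outcome_se, n_snps)
    eaf = rng.uniform(0.1, 0.9, n_snps)

    from scipy import stats as _st

    exposure, outcome = [], []
    for j in range(n_snps):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        snp = f"rs{seed % 1000}{j:05d}"
        exposure.append(
            GwasSummary(
                snp, ea, oa, float(eaf[j]), float(bx_obs[j]), exposure_se,
                float(np.clip(2 * _st.norm.sf(abs(bx_obs[j]) / exposure_se), 1e-300, 1)),
                n_exposure,
            )
        )
        outcome.append(
            GwasSummary(
                snp, ea, oa, float(np.clip(eaf[j] + rng.normal(0, 0.01), 0.01, 0.99)),
                float(by_obs[j]), outcome_se,
                float(np.clip(2 * _st.norm.sf(abs(by_obs[j]) / outcome_se), 1e-300, 1)),
                n_outcome,
            )
        )
    return exposure, outcome


# --------------------------------------------------------------------------
# TSV interchange


def write_cohort_tsvs(ds: CohortDataset, outdir) -> dict:
    """Write one cohort's beta/phenotype/truth tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / f"{ds.cohort_id}_beta.tsv",
        "pheno": outdir / f"{ds.cohort_id}_pheno.tsv",
        "truth": outdir / f"{ds.cohort_id}_truth.tsv",
        "cells": outdir / f"{ds.cohort_id}_cell_fractions.tsv",
    }
    ds.beta.to_csv(paths["beta"], sep="\t", index_label="cpg_id")
    pheno = ds.covariates.copy()
    pheno.insert(0, "time", ds.time)
    pheno.insert(1, "event", ds.event)
    pheno.insert(2, "time2", ds.time2)
    pheno.insert(3, "event2", ds.event2)
    pheno.to_csv(paths["pheno"], sep="\t", index_label="sample_id")
    ds.truth.to_frame().to_csv(paths["truth"], sep="\t", index_label="cpg_id")
    ds.cell_fractions_true.to_csv(paths["cells"], sep="\t", index_label="sample_id")
    return paths


def read_cohort_tsvs(cohort_id: str, indir) -> CohortDataset:
    indir = Path(indir)
    beta = pd.read_csv(indir / f"{cohort_id}_beta.tsv", sep="\t", index_col="cpg_id")
    pheno = pd.read_csv(indir / f"{cohort_id}_pheno.tsv", sep="\t", index_col="sample_id")
    truth = pd.read_csv(indir / f"{cohort_id}_truth.tsv", sep="\t", index_col="cpg_id")
    cells = pd.read_csv(
        indir / f"{cohort_id}_cell_fractions.tsv", sep="\t", index_col="sample_id"
    )
    cov = pheno.drop(columns=["time", "event", "time2", "event2"])
    return CohortDataset(
        cohort_id=cohort_id,
        beta=beta,
        covariates=cov,
        time=pheno["time"],
        event=pheno["event"],
        time2=pheno["time2"],
        event2=pheno["event2"],
        cell_fractions_true=cells,
        truth=truth["true_loghr"],
    )


def write_gwas_tsv(rows: list[GwasSummary], path) -> None:
    pd.DataFrame([vars(r) for r in rows]).to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path) -> list[GwasSummary]:
    df = pd.read_csv(path, sep="\t")
    return [GwasSummary(**rec) for rec in df.to_dict("records")]
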