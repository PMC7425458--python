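"""End-to-end orchestration over plain-TSV interchange files.

Each stage reads its upstream tables from the working directory and writes
its own, so any stage can be re-run (byte-identically, given the same
config and seed) and inspected with ordinary text tools. ``run_pipeline``
executes the selected stages in fixed order and records a manifest with
the config hash, seed, package versions and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cell_deconv, enrich_clocks, meta_analysis, mendelian_rand, paf, probe_qc
from . import qtl as qtl_mod
from . import survival_ewas, synthgen

STAGE_ORDER = [
    "simulate", "qc", "ewas", "meta", "paf", "mr", "deconv", "qtl", "enrich", "clock",
]


class DependencyError(RuntimeError):
    """An upstream stage's output is missing."""

    def __init__(self, stage: str, path):
        super().__init__(f"stage {stage!r} requires missing input {path}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds mirror the analysis defaults."""

    workdir: str = "pipeline_run"
    stages: tuple[str, ...] = tuple(STAGE_ORDER)
    model: str = "full"
    n_cohorts: int = 4
    n_subjects_per_cohort: int = 200
    n_cpgs: int = 300
    n_causal: int = 5
    causal_loghr: float = 1.0
    #: demo baseline chosen so that, with the causal sites shifting the mean
    #: linear predictor by ~+2.5, overall mortality lands near 25%
    baseline_hazard: float = 0.0025
    min_cohorts: int = 3
    iqr_min: float = 0.001
    max_missing: float = 0.10
    fdr_q: float = 0.05
    retain_p: float = 1e-4
    sig_p: float = 1e-14
    cis_bp: int = 500_000
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.fdr_q < 1 and 0 <= self.max_missing <= 1):
            raise ValueError("threshold out of range")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _need(stage: str, path: Path) -> Path:
    if not path.exists():
        raise DependencyError(stage, path)
    return path


def _cohort_ids(cfg: RunConfig) -> list[str]:
    return [f"COH{c + 1:02d}" for c in range(cfg.n_cohorts)]


def _load_cohorts(cfg: RunConfig, wd: Path, stage: str) -> list[synthgen.CohortDataset]:
    for cid in _cohort_ids(cfg):
        _need(stage, wd / f"{cid}_beta.tsv")
    return [synthgen.read_cohort_tsvs(cid, wd) for cid in _cohort_ids(cfg)]


# --------------------------------------------------------------------- stages


def stage_simulate(cfg: RunConfig, wd: Path) -> dict:
    causal = tuple(
        synthgen.cpg_name(i)
        for i in np.linspace(20, cfg.n_cpgs - 1, cfg.n_causal, dtype=int)
    )
    sim = synthgen.SimConfig(
        n_cohorts=cfg.n_cohorts,
        n_subjects_per_cohort=cfg.n_subjects_per_cohort,
        n_cpgs=cfg.n_cpgs,
        causal_cpg_ids=causal,
        causal_loghr_per_unit_beta=cfg.causal_loghr,
        causal_bimodal_delta=3.5,
        baseline_hazard_scale=cfg.baseline_hazard,
        seed=cfg.seed,
    )
    ref = synthgen.generate_reference_matrix(n_cpgs=cfg.n_cpgs, seed=cfg.seed)
    cohorts = synthgen.generate_cohorts(sim, ref)
    for ds in cohorts:
        synthgen.write_cohort_tsvs(ds, wd)
    ref.to_frame().to_csv(wd / "reference_matrix.tsv", sep="\t", index_label="cell_type")
    annot = synthgen.generate_annotation(ref.cpg_ids, seed=cfg.seed)
    # keep simulated causal CpGs clear of exclusion flags so they reach meta
    for col in ("is_control", "is_noncpg", "is_crossreactive", "snp_within_10bp"):
        annot.loc[list(causal), col] = False
    annot.loc[list(causal), "chrom"] = "1"
    annot.to_csv(wd / "annotation.tsv", sep="\t")
    return {"cohorts": len(cohorts), "cpgs": cfg.n_cpgs}


def stage_qc(cfg: RunConfig, wd: Path) -> dict:
    cohorts = _load_cohorts(cfg, wd, "qc")
    annot = pd.read_csv(_need("qc", wd / "annotation.tsv"), sep="\t", index_col="cpg_id")
    kept, counts = probe_qc.filter_probes(
        cohorts, annot, cfg.min_cohorts, cfg.iqr_min, cfg.max_missing
    )
    pd.Series(kept, name="cpg_id").to_csv(wd / "kept_cpgs.tsv", sep="\t", index=False)
    probe_qc.exclusion_report(counts).to_csv(wd / "exclusion_report.tsv", sep="\t", index=False)
    return {"kept": len(kept)}


def stage_ewas(cfg: RunConfig, wd: Path) -> dict:
    cohorts = _load_cohorts(cfg, wd, "ewas")
    kept = pd.read_csv(_need("ewas", wd / "kept_cpgs.tsv"), sep="\t")["cpg_id"].tolist()
    ref = _read_reference(wd, "ewas")
    results = []
    for ds in cohorts:
        ds.beta = ds.beta.loc[[c for c in kept if c in ds.beta.index]]
        fracs = cell_deconv.estimate_fractions_cohort(ds.beta, ref)
        for model in ("basic", "full"):
            results.append(
                survival_ewas.ewas_cohort(ds, model=model, cell_fractions=fracs)
            )
    res = pd.concat(results, ignore_index=True)
    res.to_csv(wd / "ewas_results.tsv", sep="\t", index=False)
    return {"rows": len(res)}


def _read_reference(wd: Path, stage: str) -> synthgen.ReferenceMatrix:
    df = pd.read_csv(_need(stage, wd / "reference_matrix.tsv"), sep="\t", index_col="cell_type")
    ref = synthgen.ReferenceMatrix(
        list(df.index), list(df.columns), df.to_numpy(float), list(df.columns[:0]),
    )
    # recover the discriminating subset: marker CpGs have a 0.9/0.1 pattern
    prof = df.to_numpy(float)
    disc = [c for j, c in enumerate(df.columns)
            if prof[:, j].max() >= 0.85 and np.sort(prof[:, j])[-2] <= 0.15]
    ref.discriminating = disc
    return ref


def stage_meta(cfg: RunConfig, wd: Path) -> dict:
    res = pd.read_csv(_need("meta", wd / "ewas_results.tsv"), sep="\t")
    out_rows = {}
    for model, grp in res.groupby("model"):
        meta = meta_analysis.ivw_fixed_effects(grp, cfg.min_cohorts)
        lam = meta_analysis.genomic_inflation(meta["pval"]) if not meta.empty else np.nan
        meta["lambda_meta"] = lam
        meta.to_csv(wd / f"meta_{model}.tsv", sep="\t", index=False)
        stats = meta_analysis.cohort_summary(grp)
        stats.to_csv(wd / f"cohort_stats_{model}.tsv", sep="\t")
        try:
            sens, dropped = meta_analysis.sensitivity_exclusion(stats, grp, min_cohorts=1)
        except ValueError:
            # every cohort tripped the death/inflation bounds; record that
            sens = meta.iloc[0:0]
        sens.to_csv(wd / f"meta_{model}_sensitivity.tsv", sep="\t", index=False)
        loo = meta_analysis.leave_one_out(grp, min_cohorts=1)
        loo.to_csv(wd / f"meta_{model}_loo.tsv", sep="\t", index=False)
        out_rows[model] = len(meta)
    return {"cpgs_pooled": out_rows}


def stage_paf(cfg: RunConfig, wd: Path) -> dict:
    cohorts = _load_cohorts(cfg, wd, "paf")
    meta = pd.read_csv(_need("paf", wd / f"meta_{cfg.model}.tsv"), sep="\t")
    top = meta[meta["fdr_sig"]]["cpg_id"].tolist() or meta.nsmallest(3, "pval")["cpg_id"].tolist()
    rows = []
    for ds in cohorts:
        for cpg in top:
            try:
                rows.append(paf.paf_from_cohort(ds, cpg, cfg.model))
            except (RuntimeError, ValueError):
                continue
    out = pd.DataFrame(rows, columns=["cpg_id", "cohort_id", "pc", "rr", "paf"])
    out.to_csv(wd / "paf.tsv", sep="\t", index=False)
    return {"rows": len(out)}


def stage_mr(cfg: RunConfig, wd: Path) -> dict:
    _need("mr", wd / f"meta_{cfg.model}.tsv")
    expo, outc = synthgen.generate_mr_summaries(
        n_snps=25, true_effect=0.3, pleiotropy_frac=0.2, pleiotropy_mean=0.05,
        seed=cfg.seed + 101, palindromic_frac=0.1,
    )
    synthgen.write_gwas_tsv(expo, wd / "mr_exposure.tsv")
    synthgen.write_gwas_tsv(outc, wd / "mr_outcome.tsv")
    inst = mendelian_rand.harmonize(expo, outc)
    res = mendelian_rand.run_all_estimators(inst, n_boot=200, seed=cfg.seed + 102)
    single = mendelian_rand.InstrumentSet(
        inst.snp_ids[:1], inst.bx[:1], inst.sx[:1], inst.by[:1], inst.sy[:1]
    )
    wald = mendelian_rand.wald_ratio(single)
    res = pd.concat(
        [res, pd.DataFrame([{"method": "wald_ratio_first_snp", **wald,
                             "n_snps": 1, "n_dropped_palindromic": inst.n_dropped_palindromic}])],
        ignore_index=True,
    )
    res.to_csv(wd / "mr_results.tsv", sep="\t", index=False)
    return {"methods": len(res)}


def stage_deconv(cfg: RunConfig, wd: Path) -> dict:
    cohorts = _load_cohorts(cfg, wd, "deconv")
    ref = _read_reference(wd, "deconv")
    meta = pd.read_csv(_need("deconv", wd / f"meta_{cfg.model}.tsv"), sep="\t")
    top = meta.nsmallest(1, "pval")["cpg_id"].iloc[0] if len(meta) else None
    nlr_rows, frac_frames = [], []
    for ds in cohorts:
        fracs = cell_deconv.estimate_fractions_cohort(ds.beta, ref)
        fracs.to_csv(wd / f"{ds.cohort_id}_fractions.tsv", sep="\t", index_label="sample_id")
        frac_frames.append(fracs)
        nlr = cell_deconv.compute_nlr(fracs)
        tab = cell_deconv.nlr_mortality_models(ds, nlr, top, fracs, cfg.model)
        tab.insert(0, "cohort_id", ds.cohort_id)
        nlr_rows.append(tab)
    out = pd.concat(nlr_rows, ignore_index=True)
    out.to_csv(wd / "nlr_mortality.tsv", sep="\t", index=False)
    return {"samples": int(sum(f.shape[0] for f in frac_frames))}


def stage_qtl(cfg: RunConfig, wd: Path) -> dict:
    cohorts = _load_cohorts(cfg, wd, "qtl")
    annot = pd.read_csv(_need("qtl", wd / "annotation.tsv"), sep="\t", index_col="cpg_id")
    meta = pd.read_csv(_need("qtl", wd / f"meta_{cfg.model}.tsv"), sep="\t")
    ds = cohorts[0]
    rng = np.random.default_rng(cfg.seed + 201)
    sig = meta[meta["fdr_sig"]]["cpg_id"].tolist() or meta.nsmallest(3, "pval")["cpg_id"].tolist()
    sig = [c for c in sig if c in ds.beta.index][:5]
    samples = ds.beta.columns
    n = len(samples)
    # genotypes partially driving the focal CpGs, plus null SNPs
    geno = {}
    for i, cpg in enumerate(sig):
        m = ds.beta.loc[cpg].fillna(ds.beta.loc[cpg].mean()).to_numpy(float)
        dose = np.clip(np.round(2 * m + rng.normal(0, 0.3, n)), 0, 2)
        geno[f"snp_{cpg}"] = dose
    for j in range(20):
        geno[f"snp_null{j:02d}"] = rng.binomial(2, 0.3, n).astype(float)
    G = pd.DataFrame(geno, index=samples).T
    covs = pd.DataFrame(
        {
            "age": ds.covariates["age_years"].astype(float),
            "sex": ds.covariates["sex"].astype(float),
            "bmi": ds.covariates["bmi"].astype(float),
        },
        index=samples,
    )
    covs = pd.concat([covs, ds.cell_fractions_true.iloc[:, :-1]], axis=1)
    me = qtl_mod.meqtl_scan(
        ds.beta.loc[sig].fillna(ds.beta.loc[sig].mean(axis=1).mean()),
        G, covs, retain_p=cfg.retain_p, sig_p=cfg.sig_p,
    )
    me.to_csv(wd / "meqtl.tsv", sep="\t", index=False)

    # expression probes: one cis partner per focal CpG plus distant probes
    expr, gene_rows = {}, []
    for i, cpg in enumerate(sig):
        m = ds.beta.loc[cpg].fillna(ds.beta.loc[cpg].mean()).to_numpy(float)
        expr[f"probe_{cpg}"] = 8 - 1.5 * m + rng.normal(0, 0.2, n)
        pos = int(annot.loc[cpg, "pos"])
        gene_rows.append(
            {"probe": f"probe_{cpg}", "chrom": annot.loc[cpg, "chrom"],
             "start": pos + 100_000, "end": pos + 150_000}
        )
        expr[f"probe_far{i}"] = rng.normal(8, 0.5, n)
        gene_rows.append(
            {"probe": f"probe_far{i}", "chrom": annot.loc[cpg, "chrom"],
             "start": pos + 800_000, "end": pos + 850_000}
        )
    E = pd.DataFrame(expr, index=samples).T
    gene_annot = pd.DataFrame(gene_rows).set_index("probe")
    batch = pd.Series(rng.choice(["B1", "B2", "B3"], n), index=samples)
    eq = qtl_mod.eqtm_scan(
        ds.beta.loc[sig].fillna(0.5), E, covs, batch, annot, gene_annot, cfg.cis_bp
    )
    eq.to_csv(wd / "eqtm.tsv", sep="\t", index=False)
    return {"meqtl_retained": len(me), "eqtm_pairs": len(eq)}


def stage_enrich(cfg: RunConfig, wd: Path) -> dict:
    annot = pd.read_csv(_need("enrich", wd / "annotation.tsv"), sep="\t", index_col="cpg_id")
    meta = pd.read_csv(_need("enrich", wd / f"meta_{cfg.model}.tsv"), sep="\t")
    kept = pd.read_csv(_need("enrich", wd / "kept_cpgs.tsv"), sep="\t")["cpg_id"]
    sig = meta[meta["fdr_sig"]]["cpg_id"]
    table = enrich_clocks.fisher_enrichment(set(sig), set(kept), annot)
    table.to_csv(wd / "enrichment.tsv", sep="\t", index=False)
    return {"categories": len(table)}


def stage_clock(cfg: RunConfig, wd: Path) -> dict:
    cohorts = _load_cohorts(cfg, wd, "clock")
    meta = pd.read_csv(_need("clock", wd / f"meta_{cfg.model}.tsv"), sep="\t")
    rng = np.random.default_rng(cfg.seed + 301)
    ds = cohorts[0]
    clock_ids = list(rng.choice(ds.beta.index, size=min(30, len(ds.beta.index)), replace=False))
    clock = enrich_clocks.ClockDefinition(
        "synthetic_demo_clock",
        {c: float(w) for c, w in zip(clock_ids, rng.normal(0, 8, len(clock_ids)))},
        intercept=60.0,
    )
    pd.DataFrame(
        [("INTERCEPT", clock.intercept)] + list(clock.cpg_weights.items())
    ).to_csv(wd / "clock_coefficients.tsv", sep="\t", index=False, header=False)
    top = meta.nsmallest(1, "pval")["cpg_id"].iloc[0]
    rows = []
    for ds in cohorts:
        score = enrich_clocks.apply_clock(ds.beta, clock)
        accel = enrich_clocks.age_acceleration(
            score, ds.covariates["age_years"], mode="difference"
        )
        adj = pd.DataFrame({"clock_accel": accel})
        rows.append(enrich_clocks.adjusted_mortality_model(ds, top, adj, cfg.model))
        pd.DataFrame({"clock": score, "acceleration": accel}).to_csv(
            wd / f"{ds.cohort_id}_clock_scores.tsv", sep="\t", index_label="sample_id"
        )
    pd.DataFrame(rows).to_csv(wd / "clock_adjusted_mortality.tsv", sep="\t", index=False)
    return {"cohorts": len(rows)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "ewas": stage_ewas,
    "meta": stage_meta,
    "paf": stage_paf,
    "mr": stage_mr,
    "deconv": stage_deconv,
    "qtl": stage_qtl,
    "enrich": stage_enrich,
    "clock": stage_clock,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in fixed order; returns the manifest."""
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "methmort": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        manifest["stages"][stage] = _STAGE_FUNCS[stage](config, wd)
    with open(wd / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
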