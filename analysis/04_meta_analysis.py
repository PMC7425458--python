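"""Inverse-variance fixed-effects meta-analysis with multiplicity control,
heterogeneity, genomic inflation, leave-one-out and cohort-exclusion
sensitivity checks."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import WORKDIR, demo_config  # noqa: E402

from methmort.pipeline import run_pipeline  # noqa: E402
from methmort.survival_ewas import hr_per_10pct  # noqa: E402


def main():
    run_pipeline(demo_config(["meta"]))
    for model in ("basic", "full"):
        meta = pd.read_csv(WORKDIR / f"meta_{model}.tsv", sep="\t")
        lam = meta["lambda_meta"].iloc[0]
        sig = meta[meta["fdr_sig"]]
        print(
            f"model={model}: {len(meta)} CpGs pooled, lambda={lam:.2f}, "
            f"{int(meta['bonferroni_sig'].sum())} Bonferroni / {len(sig)} FDR significant"
        )
        for _, row in sig.nsmallest(5, "pval").iterrows():
            print(
                f"  {row['cpg_id']}: HR/10% = {hr_per_10pct(row['beta_pooled']):.2f}, "
                f"p = {row['pval']:.2e}, I2 = {row['I2']:.0f}%, "
                f"directions {row['direction_string']}"
            )
    loo = pd.read_csv(WORKDIR / "meta_full_loo.tsv", sep="\t")
    full = pd.read_csv(WORKDIR / "meta_full.tsv", sep="\t")
    if not loo.empty and not full.empty:
        top_cpg = full.nsmallest(1, "pval")["cpg_id"].iloc[0]
        top = loo[loo["cpg_id"] == top_cpg]
        spread = top["beta_pooled"].max() - top["beta_pooled"].min()
        print(f"leave-one-out spread for top CpG {top_cpg}: {spread:.3f} log-HR")


if __name__ == "__main__":
    main()
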