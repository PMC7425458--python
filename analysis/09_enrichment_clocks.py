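"""Genomic-feature enrichment of significant CpGs and clock-adjusted
mortality models with a synthetic demonstration clock."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import WORKDIR, demo_config  # noqa: E402

from methmort.pipeline import run_pipeline  # noqa: E402


def main():
    run_pipeline(demo_config(["enrich", "clock"]))
    enr = pd.read_csv(WORKDIR / "enrichment.tsv", sep="\t")
    print("top enrichment categories (one-sided Fisher, BH-FDR):")
    for _, row in enr.nsmallest(4, "pval").iterrows():
        print(
            f"  {row['category']:>28}: OR {row['odds_ratio']:.2f}, "
            f"p = {row['pval']:.3f}, q = {row['fdr_q']:.3f}"
        )
    adj = pd.read_csv(WORKDIR / "clock_adjusted_mortality.tsv", sep="\t")
    print("top CpG's mortality coefficient with clock-acceleration adjustment:")
    for _, row in adj.iterrows():
        if row["converged"]:
            print(f"  {row['cohort_id']}: log-HR {row['beta']:+.2f} "
                  f"(se {row['se']:.2f}), p = {row['pval']:.3f}")


if __name__ == "__main__":
    main()
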