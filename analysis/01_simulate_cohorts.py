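"""Simulate the demo consortium: 4 cohorts of 450K-style blood methylation
with right-censored mortality, five causal CpGs, and a probe manifest."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import WORKDIR, demo_config  # noqa: E402

from methmort.pipeline import run_pipeline  # noqa: E402


def main():
    cfg = demo_config(["simulate"])
    manifest = run_pipeline(cfg)
    print(f"simulated {manifest['stages']['simulate']}")
    for c in range(cfg.n_cohorts):
        cid = f"COH{c + 1:02d}"
        pheno = pd.read_csv(WORKDIR / f"{cid}_pheno.tsv", sep="\t", index_col="sample_id")
        print(
            f"  {cid}: n={len(pheno)}, deaths={int(pheno['event'].sum())} "
            f"({pheno['event'].mean():.0%}), mean follow-up {pheno['time'].mean():.1f}y"
        )
    truth = pd.read_csv(WORKDIR / "COH01_truth.tsv", sep="\t", index_col="cpg_id")
    causal = truth[truth["true_loghr"] != 0]
    print(f"causal CpGs ({len(causal)}): {', '.join(causal.index)}")


if __name__ == "__main__":
    main()
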