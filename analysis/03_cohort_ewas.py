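"""Per-cohort epigenome-wide Cox screens (basic and fully-adjusted
covariate sets, cell proportions estimated by constrained projection)."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import WORKDIR, demo_config  # noqa: E402

from methmort.meta_analysis import cohort_summary  # noqa: E402
from methmort.pipeline import run_pipeline  # noqa: E402


def main():
    run_pipeline(demo_config(["ewas"]))
    res = pd.read_csv(WORKDIR / "ewas_results.tsv", sep="\t")
    print(f"{len(res)} per-CpG fits across cohorts and models")
    for model, grp in res.groupby("model"):
        summ = cohort_summary(grp)
        print(f"model={model}:")
        for cid, row in summ.iterrows():
            conv = grp[grp["cohort_id"] == cid]["converged"].mean()
            print(
                f"  {cid}: deaths {row['death_prop']:.0%}, "
                f"lambda {row['lambda']:.2f}, converged {conv:.0%}"
            )


if __name__ == "__main__":
    main()
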