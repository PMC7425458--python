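"""Miettinen's population attributable fraction for above-mean methylation
at the top mortality CpGs, per cohort."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import WORKDIR, demo_config  # noqa: E402

from methmort.pipeline import run_pipeline  # noqa: E402


def main():
    run_pipeline(demo_config(["paf"]))
    paf = pd.read_csv(WORKDIR / "paf.tsv", sep="\t")
    if paf.empty:
        print("no converged PAF estimates")
        return
    print("per-CpG, per-cohort attributable fractions (case-based formula):")
    for cpg, grp in paf.groupby("cpg_id"):
        lo, hi = grp["paf"].min(), grp["paf"].max()
        print(
            f"  {cpg}: PAF {lo:+.1%} to {hi:+.1%} "
            f"(RR {grp['rr'].min():.2f}-{grp['rr'].max():.2f})"
        )


if __name__ == "__main__":
    main()
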