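"""meQTL and eQTM scans around the top mortality CpGs with cis/trans
classification at the 500 kb rule."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import WORKDIR, demo_config  # noqa: E402

from methmort.pipeline import run_pipeline  # noqa: E402


def main():
    run_pipeline(demo_config(["qtl"]))
    me = pd.read_csv(WORKDIR / "meqtl.tsv", sep="\t")
    print(f"meQTL pairs retained at p<1e-4: {len(me)}; "
          f"genome-wide significant (p<1e-14): {int(me['significant'].sum())}")
    eq = pd.read_csv(WORKDIR / "eqtm.tsv", sep="\t")
    for _, row in eq.iterrows():
        print(
            f"  eQTM {row['cpg_id']} ~ {row['partner_id']}: "
            f"coef {row['beta']:+.2f}, p = {row['pval']:.2e}, "
            f"{row['cis_trans']} ({row['distance']/1000:.0f} kb)"
        )


if __name__ == "__main__":
    main()
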