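"""Apply the consortium probe-exclusion cascade and report the tally."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import WORKDIR, demo_config  # noqa: E402

from methmort.pipeline import run_pipeline  # noqa: E402


def main():
    manifest = run_pipeline(demo_config(["qc"]))
    report = pd.read_csv(WORKDIR / "exclusion_report.tsv", sep="\t")
    print("probe exclusion cascade (first matching rule wins):")
    for _, row in report.iterrows():
        print(f"  {row['rule']:>18}: {row['n_probes']}")
    print(f"kept for analysis: {manifest['stages']['qc']['kept']}")


if __name__ == "__main__":
    main()
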