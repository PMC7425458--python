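"""Shared configuration for the numbered analysis drivers.

All drivers operate on the same demo consortium written under
``results/demo``: 4 cohorts x 200 subjects x 300 CpGs with 5 causal sites
(log-HR 1.0 per unit beta, bimodal meQTL-driven), ~25% mortality. Run the
drivers in order; each stage reads the previous one's TSVs.
"""

from pathlib import Path

from methmort.pipeline import RunConfig

WORKDIR = Path("results/demo")


def demo_config(stages) -> RunConfig:
    return RunConfig(
        workdir=str(WORKDIR),
        stages=tuple(stages),
        n_cohorts=4,
        n_subjects_per_cohort=200,
        n_cpgs=300,
        n_causal=5,
        causal_loghr=1.0,
        seed=0,
    )
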