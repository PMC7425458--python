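"""Consortium-level probe exclusion ahead of meta-analysis.

Probes are removed in a fixed cascade, each probe tallied under the FIRST
rule that removes it, so the per-rule counts always add up:

1. control probes
2. non-CpG probes
3. allosomal (chr X/Y)
4. cross-reactive probes
5. underlying SNP within 10 bp
6. non-varying (pooled IQR below ``iqr_min``)
7. missingness at or above ``max_missing``
8. non-converging cohort fits (flag supplied by the EWAS stage)
9. available in fewer than ``min_cohorts`` cohorts
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RULES = (
    "control",
    "noncpg",
    "allosomal",
    "crossreactive",
    "snp_within_10bp",
    "non_varying",
    "missingness",
    "non_converging",
    "too_few_cohorts",
)


class AnnotationError(KeyError):
    """A CpG in the data is absent from the annotation manifest."""


def filter_probes(
    beta_by_cohort,
    annot: pd.DataFrame,
    min_cohorts: int = 4,
    iqr_min: float = 0.001,
    max_missing: float = 0.10,
    nonconverged: set | None = None,
) -> tuple[list[str], dict]:
    """Apply the exclusion cascade.

    Parameters
    ----------
    beta_by_cohort : list of CohortDataset (or of CpG x sample DataFrames)
    annot : annotation with boolean flag columns and ``chrom``
    min_cohorts : minimum number of cohorts a CpG must be observed in
        (default 4, i.e. "more than three"; pass 3 for the laxer reading)
    nonconverged : CpG ids flagged non-converging by the survival stage

    Returns ``(kept_ids, counts)`` where ``counts`` maps each rule name to
    the number of probes it removed (plus ``"kept"``).
    """
    betas = [ds.beta if hasattr(ds, "beta") else ds for ds in beta_by_cohort]
    all_ids = sorted(set().union(*[set(b.index) for b in betas]))
    unknown = [c for c in all_ids if c not in annot.index]
    if unknown:
        raise AnnotationError(f"CpGs missing from annotation: {unknown[:10]}")
    nonconverged = nonconverged or set()

    ann = annot.loc[all_ids]
    # IQR over all available sample values pooled across cohorts; with a
    # handful of cohorts a medians-based variant degenerates, so the rule is
    # computed on the full pooled distribution (deterministic either way)
    pooled = pd.concat([b.reindex(all_ids) for b in betas], axis=1)
    q3 = pooled.quantile(0.75, axis=1)
    q1 = pooled.quantile(0.25, axis=1)
    pooled_iqr = (q3 - q1).fillna(0.0)

    miss_frac = pooled.isna().mean(axis=1)
    n_cohorts_avail = pd.Series(0, index=all_ids)
    for b in betas:
        present = b.notna().any(axis=1).reindex(all_ids, fill_value=False)
        n_cohorts_avail += present.astype(int)

    counts = {r: 0 for r in RULES}
    kept = []
    for c in all_ids:
        row = ann.loc[c]
        if row["is_control"]:
            counts["control"] += 1
        elif row["is_noncpg"]:
            counts["noncpg"] += 1
        elif str(row["chrom"]) in ("X", "Y"):
            counts["allosomal"] += 1
        elif row["is_crossreactive"]:
            counts["crossreactive"] += 1
        elif row["snp_within_10bp"]:
            counts["snp_within_10bp"] += 1
        elif pooled_iqr[c] < iqr_min:
            counts["non_varying"] += 1
        elif miss_frac[c] >= max_missing:
            counts["missingness"] += 1
        elif c in nonconverged:
            counts["non_converging"] += 1
        elif n_cohorts_avail[c] < min_cohorts:
            counts["too_few_cohorts"] += 1
        else:
            kept.append(c)
    counts["kept"] = len(kept)
    return kept, counts


def exclusion_report(counts: dict) -> pd.DataFrame:
    """Per-rule tally as a tidy table."""
    return pd.DataFrame(
        {"rule": list(counts.keys()), "n_probes": list(counts.values())}
    )
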