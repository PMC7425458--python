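"""Reference-based leukocyte deconvolution and the neutrophil-lymphocyte
ratio.

Fractions are estimated by constrained projection: minimize
``||R^T w - beta||^2`` over ``w >= 0, sum(w) <= 1`` (Houseman-style), then
renormalize to sum 1 for reporting. The quadratic program is solved as a
nonnegative least-squares problem with a penalty row enforcing the simplex
constraint through a slack compartment, which is exact for noiseless
mixtures.

The granulocyte compartment stands in for neutrophils when forming the
NLR (the whole-blood reference resolves granulocytes, not neutrophils).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .synthgen import LYMPHOID_TYPES, ReferenceMatrix

_PENALTY = 1e6


class RankDeficientReferenceError(ValueError):
    """Reference profiles are collinear on the shared CpGs."""


def estimate_fractions(beta_sample: pd.Series, ref: ReferenceMatrix) -> pd.Series:
    """Cell fractions for one sample's CpG beta vector.

    Uses the CpGs shared between the sample vector and the reference
    (dropping missing values). Requires at least as many shared
    discriminating CpGs as cell types and a full-column-rank design.
    """
    shared = [c for c in ref.cpg_ids if c in beta_sample.index]
    y = beta_sample.loc[shared].astype(float)
    shared = [c for c, v in zip(shared, y) if np.isfinite(v)]
    if len(shared) < len(ref.cell_types):
        raise ValueError("fewer shared CpGs than cell types")
    pos = {c: i for i, c in enumerate(ref.cpg_ids)}
    A = ref.profiles[:, [pos[c] for c in shared]].T  # CpG x type
    if np.linalg.matrix_rank(A, tol=1e-8) < len(ref.cell_types):
        raise RankDeficientReferenceError(
            "reference matrix rank deficient on shared CpGs"
        )
    b = beta_sample.loc[shared].to_numpy(float)
    K = A.shape[1]
    # augmented NNLS: extra slack column + penalty row pin sum(w)+s = 1
    Aa = np.zeros((A.shape[0] + 1, K + 1))
    Aa[:-1, :K] = A
    Aa[-1, :] = _PENALTY
    ba = np.concatenate([b, [_PENALTY]])
    w, _ = nnls(Aa, ba)
    w = w[:K]
    total = w.sum()
    if total > 1 + 1e-8:
        w = w / total
    frac = w / w.sum() if w.sum() > 0 else w
    return pd.Series(frac, index=ref.cell_types, name=beta_sample.name)


def estimate_fractions_cohort(
    beta: pd.DataFrame, ref: ReferenceMatrix, use_discriminating: bool = True
) -> pd.DataFrame:
    """Per-sample deconvolution of a CpG x sample matrix.

    By default the projection uses the reference's designated discriminating
    CpGs (the standard reference-based practice of selecting cell-type
    marker loci); pass ``use_discriminating=False`` to use every shared CpG.
    """
    if use_discriminating and ref.discriminating:
        ids = [c for c in ref.discriminating if c in beta.index]
        if len(ids) >= len(ref.cell_types):
            pos = {c: i for i, c in enumerate(ref.cpg_ids)}
            idx = [pos[c] for c in ids]
            ref = ReferenceMatrix(
                ref.cell_types, ids, ref.profiles[:, idx], ids,
                ref.conditioning_warning,
            )
            beta = beta.loc[ids]
    return pd.DataFrame(
        {s: estimate_fractions(beta[s], ref) for s in beta.columns}
    ).T


def compute_nlr(fractions: pd.Series | pd.DataFrame) -> float | pd.Series:
    """Neutrophil-lymphocyte ratio from estimated fractions.

    NLR = granulocyte / (CD4T + CD8T naive + CD8T memory/effector + NK + B).
    A zero lymphoid sum is undefined and returns NaN (never infinity).
    """
    if isinstance(fractions, pd.DataFrame):
        return fractions.apply(compute_nlr, axis=1).rename("nlr")
    lymph = sum(fractions.get(t, 0.0) for t in LYMPHOID_TYPES)
    gran = fractions.get("Gran", np.nan)
    if not np.isfinite(gran):
        raise KeyError("granulocyte fraction absent")
    if lymph <= 0:
        return np.nan
    return float(gran / lymph)


def nlr_mortality_models(
    cohort,
    nlr: pd.Series,
    cpg_id: str | None = None,
    cell_fractions: pd.DataFrame | None = None,
    model: str = "full",
) -> pd.DataFrame:
    """Hazard of death on NLR under three adjustment modes.

    Modes: ``without`` (no cell-fraction covariates), ``with_houseman_covars``
    (cell fractions added), ``with_cpg`` (no fractions, the chosen CpG's
    methylation added). Returns one row per mode with the NLR coefficient.
    """
    from .cox import fit_cox
    from .survival_ewas import covariate_design

    time = cohort.time.to_numpy(float)
    event = cohort.event.to_numpy(int)
    nlr_v = nlr.loc[cohort.covariates.index].to_numpy(float)
    rows = []
    modes = ["without", "with_houseman_covars"] + (["with_cpg"] if cpg_id else [])
    for mode in modes:
        cf = cell_fractions if mode == "with_houseman_covars" else None
        design = covariate_design(cohort.covariates, model, cf).to_numpy(float)
        colv = [nlr_v]
        if mode == "with_cpg":
            colv.append(cohort.beta.loc[cpg_id].to_numpy(float))
        X = np.column_stack(colv + [design])
        obs = np.all(np.isfinite(X), axis=1)
        fit = fit_cox(X[obs], time[obs], event[obs])
        rows.append(
            {
                "mode": mode,
                "coef": fit.beta[0] if fit.converged else np.nan,
                "se": fit.se[0] if fit.converged else np.nan,
                "pval": fit.pval[0] if fit.converged else np.nan,
                "converged": bool(fit.converged),
            }
        )
    return pd.DataFrame(rows)
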