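"""Miettinen's population attributable fraction for above-mean methylation.

The exposure is "methylation above the cohort mean at this CpG"; the
case-based formula PAF = pc * (RR - 1) / RR uses the exposure prevalence
among cases (deaths) together with the confounder-adjusted rate ratio, so
the estimate remains valid under covariate adjustment. The hazard ratio
from the fully-adjusted proportional-hazards fit serves as the rate ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import fit_cox
from .survival_ewas import covariate_design


@dataclass
class PafInput:
    pc: float  # exposure prevalence among cases
    rr: float  # adjusted rate/hazard ratio, exposed vs unexposed

    def __post_init__(self):
        if not 0 <= self.pc <= 1:
            raise ValueError("pc must be in [0,1]")
        if self.rr <= 0:
            raise ValueError("rr must be > 0")


def dichotomize_exposure(beta_vector) -> np.ndarray:
    """1 where the value strictly exceeds the mean of observed values."""
    v = np.asarray(beta_vector, dtype=float)
    obs = np.isfinite(v)
    if not obs.any():
        raise ValueError("all values missing")
    mean = v[obs].mean()
    out = np.zeros(v.shape, dtype=float)
    out[obs] = (v[obs] > mean).astype(float)
    out[~obs] = np.nan
    return out


def miettinen_paf(inp: PafInput) -> float:
    """PAF = pc (rr - 1)/rr; negative when the exposure is protective."""
    return inp.pc * (inp.rr - 1.0) / inp.rr


def paf_from_cohort(
    cohort,
    cpg_id: str,
    model: str = "full",
    cell_fractions: pd.DataFrame | None = None,
) -> dict:
    """Cohort-level Miettinen PAF for one CpG.

    pc is the exposed fraction among deaths; RR is the adjusted hazard
    ratio of the dichotomized exposure from the chosen covariate model.
    """
    if cohort.event.sum() == 0:
        raise ValueError("no deaths in cohort")
    expo = dichotomize_exposure(cohort.beta.loc[cpg_id].to_numpy(float))
    design = covariate_design(cohort.covariates, model, cell_fractions).to_numpy(float)
    obs = np.isfinite(expo)
    X = np.column_stack([expo[obs], design[obs]])
    time = cohort.time.to_numpy(float)[obs]
    event = cohort.event.to_numpy(int)[obs]
    fit = fit_cox(X, time, event)
    if not fit.converged:
        raise RuntimeError(f"adjusted hazard fit did not converge for {cpg_id}")
    rr = float(np.exp(fit.beta[0]))
    cases = event == 1
    pc = float(expo[obs][cases].mean())
    return {
        "cpg_id": cpg_id,
        "cohort_id": cohort.cohort_id,
        "pc": pc,
        "rr": rr,
        "paf": miettinen_paf(PafInput(pc, rr)),
    }
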