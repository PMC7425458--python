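"""Two-sample Mendelian randomization from harmonized GWAS summary
statistics.

Estimators follow the standard two-sample toolkit: the Wald ratio for a
single instrument, and MR-Egger, weighted median and weighted mode for
multi-instrument sets, whose differing identifying assumptions give
robustness to horizontal pleiotropy. Binary-outcome effects are treated as
log-odds; causal estimates are exponentiated to odds ratios for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_AMBIG_EAF = (0.42, 0.58)


@dataclass
class InstrumentSet:
    """Harmonized SNP->exposure and SNP->outcome effect/SE pairs."""

    snp_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    harmonized: bool = True
    n_dropped_palindromic: int = 0
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        for a in ("bx", "sx", "by", "sy"):
            setattr(self, a, np.asarray(getattr(self, a), dtype=float))
        k = len(self.snp_ids)
        if not all(len(getattr(self, a)) == k for a in ("bx", "sx", "by", "sy")):
            raise ValueError("field lengths differ")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValueError("SEs must be positive")

    @property
    def k(self) -> int:
        return len(self.snp_ids)


class HarmonizationError(ValueError):
    pass


def harmonize(exposure, outcome) -> InstrumentSet:
    """Align alleles across the two summary files.

    Matching effect/other alleles keep their signs; swapped alleles flip the
    outcome sign; palindromic SNPs (A/T, C/G) with allele frequency in
    (0.42, 0.58) are strand-ambiguous and dropped with a tally. Finally
    every instrument is oriented so the exposure effect is nonnegative.
    """
    out_by_id = {o.snp_id: o for o in outcome}
    shared = [e for e in exposure if e.snp_id in out_by_id]
    if not shared:
        raise HarmonizationError("no shared SNPs between exposure and outcome")
    ids, bx, sx, by, sy, dropped = [], [], [], [], [], []
    n_pal = 0
    for e in shared:
        o = out_by_id[e.snp_id]
        pair = frozenset((e.effect_allele, e.other_allele))
        if pair in _PALINDROMIC and (
            _AMBIG_EAF[0] < e.eaf < _AMBIG_EAF[1] or _AMBIG_EAF[0] < o.eaf < _AMBIG_EAF[1]
        ):
            n_pal += 1
            dropped.append(e.snp_id)
            continue
        if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            flip = 1.0
        elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
            flip = -1.0
        else:
            dropped.append(e.snp_id)  # allele mismatch, unharmonizable
            continue
        sgn = 1.0 if e.beta >= 0 else -1.0  # orient bx >= 0
        ids.append(e.snp_id)
        bx.append(sgn * e.beta)
        sx.append(e.se)
        by.append(sgn * flip * o.beta)
        sy.append(o.se)
    if not ids:
        raise HarmonizationError("no harmonizable SNPs remained")
    return InstrumentSet(ids, bx, sx, by, sy, True, n_pal, dropped)


def wald_ratio(inst: InstrumentSet) -> dict:
    """Single-instrument causal estimate by = bx * theta.

    First-order delta SE (se = sy/|bx|), the two-sample MR convention for
    strong instruments.
    """
    if inst.k != 1:
        raise ValueError("Wald ratio requires exactly one instrument")
    bx, by, sy = inst.bx[0], inst.by[0], inst.sy[0]
    if bx == 0:
        raise ZeroDivisionError("null instrument (bx = 0)")
    est = by / bx
    se = sy / abs(bx)
    p = float(np.clip(2 * stats.norm.sf(abs(est / se)), np.nextafter(0, 1), 1.0))
    return {"estimate": est, "se": se, "pval": p, "or": float(np.exp(est)),
            "ci_low": est - 1.959963984540054 * se, "ci_high": est + 1.959963984540054 * se}


def mr_egger(inst: InstrumentSet) -> dict:
    """Weighted least squares of by on bx with intercept, weights 1/sy^2.

    The slope is the causal estimate; a nonzero intercept indicates
    directional pleiotropy.
    """
    if inst.k < 3:
        raise ValueError("MR-Egger requires >= 3 instruments")
    X = sm.add_constant(inst.bx)
    res = sm.WLS(inst.by, X, weights=1.0 / inst.sy**2).fit()
    icpt, slope = res.params
    icpt_se, slope_se = res.bse
    return {
        "estimate": float(slope),
        "se": float(slope_se),
        "pval": float(res.pvalues[1]),
        "intercept": float(icpt),
        "intercept_se": float(icpt_se),
        "intercept_pval": float(res.pvalues[0]),
        "or": float(np.exp(slope)),
    }


def _ratios_weights(inst: InstrumentSet, exact_weights: bool = False):
    keep = inst.bx != 0
    r = inst.by[keep] / inst.bx[keep]
    if exact_weights:
        var = inst.sy[keep] ** 2 / inst.bx[keep] ** 2 + (
            inst.by[keep] ** 2 * inst.sx[keep] ** 2 / inst.bx[keep] ** 4
        )
        w = 1.0 / var
    else:
        w = (inst.bx[keep] / inst.sy[keep]) ** 2
    return r, w, int((~keep).sum())


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r, w = r[order], w[order]
    cw = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    cw = cw / np.sum(w)
    return float(np.interp(0.5, cw, r))


def weighted_median(
    inst: InstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
    exact_weights: bool = False,
) -> dict:
    """Weighted-median causal estimate (50% breakdown robustness).

    Weights default to (bx/sy)^2, the inverse-variance approximation of the
    per-instrument ratio; SE by parametric bootstrap over (bx, by).
    """
    if inst.k < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    r, w, _ = _ratios_weights(inst, exact_weights)
    est = _weighted_median(r, w)
    se = _bootstrap_se(inst, n_boot, seed, lambda rr, ww: _weighted_median(rr, ww),
                       exact_weights)
    p = (
        float(np.clip(2 * stats.norm.sf(abs(est / se)), np.nextafter(0, 1), 1.0))
        if se and np.isfinite(se) and se > 0
        else np.nan
    )
    return {"estimate": est, "se": se, "pval": p, "or": float(np.exp(est))}


def _silverman_bandwidth(r: np.ndarray, w: np.ndarray, factor: float) -> float:
    wn = w / w.sum()
    mu = np.sum(wn * r)
    sd = float(np.sqrt(np.sum(wn * (r - mu) ** 2)))
    med = _weighted_median(r, w)
    mad = 1.4826 * _weighted_median(np.abs(r - med), w)
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    if s == 0:
        return max(abs(mu), 1.0) * 1e-6
    return factor * 0.9 * s * len(r) ** (-0.2)


def _mode_estimate(r: np.ndarray, w: np.ndarray, factor: float, grid: int = 2048) -> float:
    h = _silverman_bandwidth(r, w, factor)
    # the argmax of a Gaussian mixture lies within the hull of its centers
    lo, hi = float(r.min()), float(r.max())
    if hi - lo < 1e-12:
        return lo
    xs = np.linspace(lo, hi, grid)
    dens = (w[None, :] * np.exp(-0.5 * ((xs[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    return float(xs[np.argmax(dens)])


def weighted_mode(
    inst: InstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    exact_weights: bool = False,
) -> dict:
    """Weighted-mode estimate: argmax of a weighted Gaussian KDE over the
    per-instrument ratios (modified-Silverman bandwidth)."""
    if inst.k < 3:
        raise ValueError("weighted mode requires >= 3 instruments")
    r, w, _ = _ratios_weights(inst, exact_weights)
    if np.all(w == 0):
        raise ValueError("all instrument weights are zero")
    est = _mode_estimate(r, w, bandwidth_factor)
    se = _bootstrap_se(
        inst, n_boot, seed, lambda rr, ww: _mode_estimate(rr, ww, bandwidth_factor),
        exact_weights,
    )
    p = (
        float(np.clip(2 * stats.norm.sf(abs(est / se)), np.nextafter(0, 1), 1.0))
        if se and np.isfinite(se) and se > 0
        else np.nan
    )
    return {"estimate": est, "se": se, "pval": p, "or": float(np.exp(est))}


def _bootstrap_se(inst, n_boot, seed, stat, exact_weights) -> float:
    """Parametric bootstrap: redraw (bx, by) from their normal sampling
    distributions, recompute the statistic."""
    if n_boot <= 0:
        return np.nan
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        bx = inst.bx + rng.normal(0, inst.sx)
        by = inst.by + rng.normal(0, inst.sy)
        boot = InstrumentSet(inst.snp_ids, bx, inst.sx, by, inst.sy)
        r, w, _ = _ratios_weights(boot, exact_weights)
        vals[b] = stat(r, w)
    return float(np.std(vals, ddof=1))


def run_all_estimators(inst: InstrumentSet, n_boot: int = 1000, seed: int = 0):
    """One row per applicable estimator for a harmonized instrument set."""
    import pandas as pd

    rows = []
    if inst.k == 1:
        res = wald_ratio(inst)
        rows.append({"method": "wald_ratio", **res})
    else:
        rows.append({"method": "mr_egger", **mr_egger(inst)})
        rows.append({"method": "weighted_median", **weighted_median(inst, n_boot, seed)})
        rows.append({"method": "weighted_mode", **weighted_mode(inst, 1.0, n_boot, seed)})
    df = pd.DataFrame(rows)
    df["n_snps"] = inst.k
    df["n_dropped_palindromic"] = inst.n_dropped_palindromic
    return df
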