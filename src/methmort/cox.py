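"""Proportional-hazards regression front end.

Thin, well-typed wrapper over the compiled partial-likelihood core in
:mod:`methmort._coxcore`. Handles sorting, tie-group construction, warm
starts, convergence/divergence flagging and the scaled-Schoenfeld
proportional-hazards diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._coxcore import cox_newton, make_groups, nll_grad_hess

DIVERGENCE_BOUND = 50.0


@dataclass
class CoxFit:
    """Result of one proportional-hazards fit.

    ``beta``/``se``/``pval`` are aligned with the columns of the design
    matrix passed to :func:`fit_cox`. ``loglik`` is the maximized log
    partial likelihood (not the negative).
    """

    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    loglik: float
    n: int
    events: int
    converged: bool
    ties: str

    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se


def _failed(p: int, n: int, events: int, ties: str) -> CoxFit:
    nan = np.full(p, np.nan)
    return CoxFit(nan.copy(), nan.copy(), nan.copy(), np.nan, n, events, False, ties)


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    init: np.ndarray | None = None,
    max_iter: int = 40,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximize the Cox partial likelihood for design matrix ``X``.

    Never raises on numerical failure: non-convergence, divergence
    (|beta| > 50) and singular information all come back with
    ``converged=False``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event)
    n, p = X.shape
    nev = int(np.sum(event == 1))
    if n == 0 or nev < 2:
        return _failed(p, n, nev, ties)
    # degenerate columns carry no information
    if np.any(np.nanstd(X, axis=0) < 1e-12):
        return _failed(p, n, nev, ties)

    order = np.argsort(-time, kind="stable")
    Xs = np.ascontiguousarray(X[order])
    # center columns: the partial likelihood is invariant, conditioning improves
    mu = Xs.mean(axis=0)
    Xs = Xs - mu
    evs = (event[order] == 1).astype(np.int8)
    starts = make_groups(time[order])

    beta0 = np.zeros(p) if init is None else np.asarray(init, dtype=np.float64).copy()
    beta, nll, grad, hess, converged = cox_newton(
        Xs, evs, starts, beta0, ties == "efron", max_iter, tol, DIVERGENCE_BOUND
    )
    if not converged:
        return _failed(p, n, nev, ties)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return _failed(p, n, nev, ties)
    var = np.diag(cov)
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        return _failed(p, n, nev, ties)
    se = np.sqrt(var)
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    # p-values live in (0,1]; clip the exact-zero underflow
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return CoxFit(beta, se, pval, -nll, n, nev, True, ties)


def loglik(X, time, event, beta, ties: str = "efron") -> float:
    """Log partial likelihood at ``beta`` (test/diagnostic helper)."""
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(-np.asarray(time, dtype=float), kind="stable")
    Xs = np.ascontiguousarray(X[order])
    evs = (np.asarray(event)[order] == 1).astype(np.int8)
    starts = make_groups(np.asarray(time, dtype=float)[order])
    nll, _, _ = nll_grad_hess(Xs, evs, starts, np.asarray(beta, dtype=float), ties == "efron")
    return -nll


def schoenfeld_ph_test(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    fit: CoxFit,
    column: int = 0,
) -> float:
    """Score test of proportional hazards for one covariate.

    Grambsch-Therneau style test: correlates the scaled Schoenfeld residual
    of ``column`` with the (centered) event time. Residuals are computed in
    the Breslow form; the time transform is the identity. Returns the
    two-sided p-value; NaN when fewer than 3 events.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if not fit.converged or int(np.sum(event == 1)) < 3:
        return np.nan

    order = np.argsort(-time, kind="stable")
    Xs = X[order] - X.mean(axis=0)
    ts = time[order]
    evs = event[order] == 1
    eta = Xs @ fit.beta
    w = np.exp(np.clip(eta, -500, 500))

    # running risk-set sums over descending time
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    S2c = np.cumsum(w * Xs[:, column] ** 2)
    # extend sums over whole tie groups so tied rows share the same risk set
    starts = make_groups(ts)
    res = []
    gtimes = []
    vs = []
    for g in range(len(starts) - 1):
        e = starts[g + 1] - 1
        xbar = S1[e, column] / S0[e]
        v = S2c[e] / S0[e] - xbar**2
        for i in range(starts[g], starts[g + 1]):
            if evs[i]:
                res.append(Xs[i, column] - xbar)
                gtimes.append(ts[i])
                vs.append(v)
    res = np.asarray(res)
    gtimes = np.asarray(gtimes)
    vs = np.asarray(vs)
    d = len(res)
    vbar = float(np.mean(vs))
    if vbar <= 0:
        return np.nan
    g = gtimes - gtimes.mean()
    # GT score statistic with the average-information approximation
    num = float(np.sum(g * res)) ** 2
    den = float(np.sum(g**2)) * vbar
    if den <= 0:
        return np.nan
    chi2 = num / den
    return float(stats.chi2.sf(chi2, df=1))
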