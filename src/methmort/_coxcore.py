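"""Low-level Cox partial-likelihood machinery.

Newton--Raphson maximization of the Cox log partial likelihood with Efron or
Breslow handling of tied event times, compiled with numba so that
epigenome-wide screens (hundreds of thousands of single-CpG fits across
cohorts and replicates) stay cheap.

Data layout contract: rows are sorted by *descending* follow-up time, so the
risk set at the event time of tie-group g is exactly the rows ``0..ends[g]-1``.
``starts``/``ends`` delimit contiguous groups of equal time.
"""

import numpy as np
from numba import njit

__all__ = ["cox_newton", "nll_grad_hess", "make_groups"]


def make_groups(time_desc: np.ndarray) -> np.ndarray:
    """Start indices of tie groups for a descending-sorted time vector.

    Returns an int64 array ``starts`` of length G+1 with ``starts[-1] == n``.
    """
    n = time_desc.shape[0]
    if n == 0:
        return np.zeros(1, dtype=np.int64)
    breaks = np.flatnonzero(np.diff(time_desc) != 0) + 1
    return np.concatenate(([0], breaks, [n])).astype(np.int64)


@njit(cache=True)
def nll_grad_hess(X, ev, starts, beta, efron):  # pragma: no cover - numba
    n, p = X.shape
    eta = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += X[i, j] * beta[j]
        eta[i] = s
    # guard against overflow in exp
    for i in range(n):
        if eta[i] > 500.0:
            eta[i] = 500.0
        elif eta[i] < -500.0:
            eta[i] = -500.0
    w = np.exp(eta)

    nll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    G = starts.shape[0] - 1
    for g in range(G):
        s = starts[g]
        e = starts[g + 1]
        # add this tie group to the running risk-set sums
        for i in range(s, e):
            wi = w[i]
            S0 += wi
            for j in range(p):
                S1[j] += wi * X[i, j]
                for k in range(j, p):
                    S2[j, k] += wi * X[i, j] * X[i, k]
        # tied-death sums within the group
        d = 0
        S0d = 0.0
        S1d = np.zeros(p)
        S2d = np.zeros((p, p))
        for i in range(s, e):
            if ev[i] == 1:
                d += 1
                wi = w[i]
                S0d += wi
                nll -= eta[i]
                for j in range(p):
                    grad[j] += X[i, j]
                    S1d[j] += wi * X[i, j]
                    for k in range(j, p):
                        S2d[j, k] += wi * X[i, j] * X[i, k]
        if d == 0:
            continue
        for l in range(d):
            f = l / d if efron else 0.0
            denom = S0 - f * S0d
            nll += np.log(denom)
            for j in range(p):
                zj = (S1[j] - f * S1d[j]) / denom
                grad[j] -= zj
            for j in range(p):
                zj = (S1[j] - f * S1d[j]) / denom
                for k in range(j, p):
                    zk = (S1[k] - f * S1d[k]) / denom
                    hess[j, k] += (S2[j, k] - f * S2d[j, k]) / denom - zj * zk
    # mirror the upper triangles
    for j in range(p):
        for k in range(j + 1, p):
            hess[k, j] = hess[j, k]
    # grad currently holds d(logL)/dbeta; return negatives consistently
    for j in range(p):
        grad[j] = -grad[j]
    return nll, grad, hess


@njit(cache=True)
def cox_newton(X, ev, starts, beta0, efron, max_iter, tol, bound):  # pragma: no cover
    p = X.shape[1]
    beta = beta0.copy()
    nll, grad, hess = nll_grad_hess(X, ev, starts, beta, efron)
    converged = False
    ok = True
    scale = abs(nll) + 1.0
    for _ in range(max_iter):
        gmax = 0.0
        for j in range(p):
            if abs(grad[j]) > gmax:
                gmax = abs(grad[j])
        if gmax < tol:
            converged = True
            break
        # Newton direction: solve H step = -grad  (hess is +ve definite for nll)
        step = np.linalg.solve(hess + 1e-12 * np.eye(p), -grad)
        alpha = 1.0
        improved = False
        for _h in range(32):
            cand = beta + alpha * step
            nll2, grad2, hess2 = nll_grad_hess(X, ev, starts, cand, efron)
            if np.isfinite(nll2) and nll2 <= nll + 1e-12 * scale:
                drop = nll - nll2
                beta = cand
                nll, grad, hess = nll2, grad2, hess2
                improved = True
                # relative-likelihood convergence (Newton is quadratic near
                # the optimum, so a vanishing drop means we are there)
                if drop < 1e-10 * scale:
                    converged = True
                break
            alpha *= 0.5
        if converged:
            # re-check the gradient is sane (not a line-search stall)
            gmax = 0.0
            for j in range(p):
                if abs(grad[j]) > gmax:
                    gmax = abs(grad[j])
            if gmax > 1e-4 * scale:
                converged = False
            else:
                break
        if not improved:
            # stalled: accept only if the gradient is already negligible
            gmax = 0.0
            for j in range(p):
                if abs(grad[j]) > gmax:
                    gmax = abs(grad[j])
            converged = gmax < 1e-6 * scale
            break
        div = False
        for j in range(p):
            if not np.isfinite(beta[j]) or abs(beta[j]) > bound:
                div = True
        if div:
            ok = False
            break
    if not ok:
        converged = False
    return beta, nll, grad, hess, converged
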