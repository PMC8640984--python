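"""Numba kernels for L0 / L0L1 / L0L2 coordinate descent with swap moves.

Objective (no intercept):

    f(beta) = 0.5 * ||y - X beta||^2
              + lam0 * #{j : beta_j != 0}
              + lam1 * sum_j |beta_j|
              + lam2 * sum_j beta_j^2

Per-coordinate closed form.  With partial residual correlation
c_j = x_j' r + a_j beta_j (a_j = ||x_j||^2) and m_j = |c_j| - lam1,
the coordinate minimiser is

    beta_j = sign(c_j) m_j / (a_j + 2 lam2)   if m_j^2 > 2 lam0 (a_j + 2 lam2)
    beta_j = 0                                otherwise,

a soft-threshold (lam1), shrink (lam2), then hard-threshold (lam0)
composite; ties at the hard threshold resolve to 0 (the sparser solution).
lam1 = lam2 = 0 recovers the pure-L0 update beta_j = c_j / a_j kept iff
c_j^2 > 2 lam0 a_j.

Cyclic descent converges to a coordinate-wise minimum; on a fixed support
that is the exact least-squares solution of the (shrunken) normal equations
(Gauss-Seidel).  Because coordinate-wise minima of the nonconvex L0
objective can be poor local solutions, converged solutions are refined by
bounded *swap* moves (remove one active coordinate, insert one inactive
one).  A swap whose one-coordinate objective estimate already improves is
accepted outright — full re-optimisation can only improve it further — and
the few best borderline candidates are trial-refitted exactly.
"""

import numpy as np
from numba import njit

# extra borderline swap candidates to trial-refit per scan
_N_TRIALS = 3


@njit(cache=True)
def _sweep(x, r, beta, colsq, lam0, lam1, lam2, active_only):
    """One coordinate-descent sweep (over the support only when
    ``active_only``); returns the largest coefficient change."""
    n, p = x.shape
    max_delta = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        aj = colsq[j]
        if aj <= 0.0:
            continue
        cj = bj * aj
        for i in range(n):
            cj += x[i, j] * r[i]
        m = abs(cj) - lam1
        newb = 0.0
        if m > 0.0:
            den = aj + 2.0 * lam2
            if m * m > 2.0 * lam0 * den:
                newb = m / den if cj > 0.0 else -m / den
        d = newb - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= d * x[i, j]
            beta[j] = newb
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def _cd_converge(x, r, beta, colsq, lam0, lam1, lam2, tol, max_iter):
    """Active-set cyclic descent: converge on the support, then run a full
    sweep; repeat until a full sweep neither changes the support nor moves
    any coefficient by more than ``tol``."""
    it = 0
    while it < max_iter:
        # polish the current support
        while it < max_iter:
            it += 1
            if _sweep(x, r, beta, colsq, lam0, lam1, lam2, True) <= tol:
                break
        nnz_before = np.count_nonzero(beta)
        delta = _sweep(x, r, beta, colsq, lam0, lam1, lam2, False)
        it += 1
        if delta <= tol and np.count_nonzero(beta) == nnz_before:
            break
    return it


@njit(cache=True)
def _penalty(beta, lam0, lam1, lam2):
    pen = 0.0
    for j in range(beta.shape[0]):
        if beta[j] != 0.0:
            pen += lam0 + lam1 * abs(beta[j]) + lam2 * beta[j] * beta[j]
    return pen


@njit(cache=True)
def _try_swaps(x, gram, r, beta, colsq, lam0, lam1, lam2, tol, max_iter, max_swaps):
    """Bounded local search over (remove j, insert k) pairs.

    For every active j the best insertion k is scored with the
    one-coordinate objective change ``delta_jk`` (an upper bound on the
    change achievable after full re-optimisation).  Scoring uses the Gram
    matrix: with c = X'r, the post-removal correlation of coordinate k is
    just c_k + beta_j G_kj, so one scan costs O(pn + |support| p).  The best
    strictly negative prediction is executed directly; otherwise the
    smallest-prediction candidates are trial-refitted and kept only if the
    exact objective improves.  Returns the number of accepted swaps.
    """
    n, p = x.shape
    cand_j = np.empty(_N_TRIALS, dtype=np.int64)
    cand_k = np.empty(_N_TRIALS, dtype=np.int64)
    cand_d = np.empty(_N_TRIALS)
    swaps = 0
    while swaps < max_swaps:
        c = x.T @ r
        n_cand = 0
        best_j = -1
        best_k = -1
        best_delta = -1e-12
        for j in range(p):
            bj = beta[j]
            if bj == 0.0:
                continue
            d_remove = (
                bj * c[j]
                + 0.5 * colsq[j] * bj * bj
                - (lam0 + lam1 * abs(bj) + lam2 * bj * bj)
            )
            k_best = -1
            gain_best = 0.0
            for k in range(p):
                if beta[k] != 0.0 or k == j or colsq[k] <= 0.0:
                    continue
                ck = c[k] + bj * gram[k, j]
                m = abs(ck) - lam1
                if m <= 0.0:
                    continue
                gain = m * m / (2.0 * (colsq[k] + 2.0 * lam2)) - lam0
                if gain > gain_best:
                    gain_best = gain
                    k_best = k
            if k_best < 0:
                continue
            delta = d_remove - gain_best
            if delta < best_delta:
                best_delta = delta
                best_j = j
                best_k = k_best
            elif n_cand < _N_TRIALS:
                cand_j[n_cand] = j
                cand_k[n_cand] = k_best
                cand_d[n_cand] = delta
                n_cand += 1
            else:
                worst = 0
                for t in range(1, _N_TRIALS):
                    if cand_d[t] > cand_d[worst]:
                        worst = t
                if delta < cand_d[worst]:
                    cand_j[worst] = j
                    cand_k[worst] = k_best
                    cand_d[worst] = delta

        if best_j >= 0:
            # certain improvement: execute and re-optimise in place
            _execute_swap(x, r, beta, colsq, lam1, lam2, best_j, best_k)
            _cd_converge(x, r, beta, colsq, lam0, lam1, lam2, tol, max_iter)
            swaps += 1
            continue

        # borderline candidates: exact trial refits
        obj = 0.5 * (r @ r) + _penalty(beta, lam0, lam1, lam2)
        accepted = False
        order = np.argsort(cand_d[:n_cand])
        for t in order:
            beta_try = beta.copy()
            r_try = r.copy()
            _execute_swap(x, r_try, beta_try, colsq, lam1, lam2, cand_j[t], cand_k[t])
            _cd_converge(x, r_try, beta_try, colsq, lam0, lam1, lam2, tol, max_iter)
            obj_try = 0.5 * (r_try @ r_try) + _penalty(beta_try, lam0, lam1, lam2)
            if obj_try < obj - 1e-10:
                beta[:] = beta_try
                r[:] = r_try
                swaps += 1
                accepted = True
                break
        if not accepted:
            break
    return swaps


@njit(cache=True)
def _execute_swap(x, r, beta, colsq, lam1, lam2, j, k):
    """Zero coordinate j, then set k to its coordinate minimiser."""
    n = x.shape[0]
    bj = beta[j]
    for i in range(n):
        r[i] += bj * x[i, j]
    beta[j] = 0.0
    ck = 0.0
    for i in range(n):
        ck += x[i, k] * r[i]
    m = abs(ck) - lam1
    bk = m / (colsq[k] + 2.0 * lam2)
    if ck < 0.0:
        bk = -bk
    beta[k] = bk
    for i in range(n):
        r[i] -= bk * x[i, k]


@njit(cache=True)
def solve_l0(x, y, beta, lam0, lam1, lam2, tol, max_iter, max_swaps):
    """Solve one path point, warm-started from ``beta`` (updated in place).
    Returns the number of accepted swap moves."""
    n, p = x.shape
    colsq = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += x[i, j] * x[i, j]
        colsq[j] = s
    r = y - x @ beta
    _cd_converge(x, r, beta, colsq, lam0, lam1, lam2, tol, max_iter)
    if max_swaps <= 0:
        return 0
    gram = x.T @ np.ascontiguousarray(x)
    return _try_swaps(x, gram, r, beta, colsq, lam0, lam1, lam2, tol, max_iter, max_swaps)


@njit(cache=True)
def solve_l0_path(x, y, lam0s, lam1, lam2, tol, max_iter, max_swaps):
    """Warm-started descending-lam0 path; returns betas of shape
    (p, len(lam0s))."""
    n, p = x.shape
    colsq = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += x[i, j] * x[i, j]
        colsq[j] = s
    use_swaps = max_swaps > 0
    gram = x.T @ np.ascontiguousarray(x) if use_swaps else np.zeros((1, 1))
    beta = np.zeros(p)
    r = y.copy()
    out = np.empty((p, lam0s.shape[0]))
    for t in range(lam0s.shape[0]):
        lam0 = lam0s[t]
        _cd_converge(x, r, beta, colsq, lam0, lam1, lam2, tol, max_iter)
        if use_swaps:
            _try_swaps(x, gram, r, beta, colsq, lam0, lam1, lam2, tol, max_iter, max_swaps)
        out[:, t] = beta
    return out


@njit(cache=True)
def objective(x, y, beta, lam0, lam1, lam2):
    """Penalised objective value (for tests and monotonicity checks)."""
    r = y - x @ beta
    return 0.5 * (r @ r) + _penalty(beta, lam0, lam1, lam2)
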