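"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the prox oracle is a
generic QP reformulation solved with SLSQP, the block-update oracle is a
derivative-free minimizer over symmetric matrices, and the metrics oracle
is an exhaustive loop over every (state, pair) tuple.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def prox_objective(z, a, W, l1, l2, mu, diag):
    z = np.asarray(z, dtype=float)
    K = len(a)
    val = 0.5 * mu * np.sum((a - z) ** 2)
    val += l2 * W * sum(
        abs(z[i] - z[j]) for i in range(K) for j in range(i + 1, K)
    )
    if not diag:
        val += l1 * W * np.sum(np.abs(z))
    return val


def qp_prox_oracle(a, W, l1, l2, mu, diag):
    """Solve the entrywise fused lasso prox as a smooth QP with auxiliary
    absolute-value variables, via SLSQP."""
    a = np.asarray(a, dtype=float)
    K = len(a)
    pairs = list(itertools.combinations(range(K), 2))
    nt = len(pairs)
    ns = 0 if diag else K
    nv = K + nt + ns
    c_t, c_s = l2 * W, l1 * W

    def f(x):
        val = 0.5 * mu * np.sum((a - x[:K]) ** 2) + c_t * np.sum(x[K:K + nt])
        if ns:
            val += c_s * np.sum(x[K + nt:])
        return val

    def g(x):
        gr = np.zeros(nv)
        gr[:K] = mu * (x[:K] - a)
        gr[K:K + nt] = c_t
        if ns:
            gr[K + nt:] = c_s
        return gr

    rows = []
    for e, (i, j) in enumerate(pairs):
        for sgn in (1, -1):
            row = np.zeros(nv)
            row[K + e] = 1
            row[i] = -sgn
            row[j] = sgn
            rows.append(row)
    for k in range(ns):
        for sgn in (1, -1):
            row = np.zeros(nv)
            row[K + nt + k] = 1
            row[k] = -sgn
            rows.append(row)
    if not rows:
        return a.copy()
    A = np.array(rows)
    x0 = np.concatenate(
        [a, [abs(a[i] - a[j]) for i, j in pairs], np.abs(a) if ns else []]
    )
    res = minimize(
        f, x0, jac=g, method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda x: A @ x, "jac": lambda x: A}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x[:K]


def theta_block_objective(T, S, Delta, Z, V, n_k, mu):
    sign, logdet = np.linalg.slogdet(T)
    if sign <= 0:
        return np.inf
    return (
        -n_k * (logdet - np.trace(S @ T))
        + mu / 2 * np.sum((T + Delta - Z + V) ** 2)
    )


def numeric_theta_minimum(S, Delta, Z, V, n_k, mu, x_init=None):
    """Derivative-free minimization of the block objective over symmetric
    matrices parametrized by their upper triangle; returns the best value."""
    p = S.shape[0]
    iu = np.triu_indices(p)

    def unvech(v):
        M = np.zeros((p, p))
        M[iu] = v
        return M + M.T - np.diag(np.diag(M))

    def obj(v):
        val = theta_block_objective(unvech(v), S, Delta, Z, V, n_k, mu)
        return val if np.isfinite(val) else 1e12

    starts = [np.eye(p)[iu]]
    if x_init is not None:
        starts.append(np.asarray(x_init)[iu])
    best = np.inf
    for x0 in starts:
        res = minimize(
            obj, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 100000,
                     "maxfev": 100000},
        )
        best = min(best, res.fun)
    return best


def brute_force_metrics(truth, estimates, tol=1e-8):
    """Metric counts by explicit loops over every (k, i<j) and (k<k', i<j)."""
    K = len(truth)
    p = truth[0].shape[0]
    tp = pos = fp = neg = 0
    for k in range(K):
        for i in range(p):
            for j in range(i + 1, p):
                t_nz = abs(truth[k][i, j]) > tol
                e_nz = abs(estimates[k][i, j]) > tol
                if t_nz:
                    pos += 1
                    tp += e_nz
                else:
                    neg += 1
                    fp += e_nz
    dtp = dpos = dfp = dneg = 0
    for k in range(K):
        for k2 in range(k + 1, K):
            for i in range(p):
                for j in range(i + 1, p):
                    t_d = abs(truth[k][i, j] - truth[k2][i, j]) > tol
                    e_d = abs(estimates[k][i, j] - estimates[k2][i, j]) > tol
                    if t_d:
                        dpos += 1
                        dtp += e_d
                    else:
                        dneg += 1
                        dfp += e_d
    return {
        "tpr": tp / pos if pos else None,
        "fpr": fp / neg if neg else None,
        "tpdr": dtp / dpos if dpos else None,
        "fpdr": dfp / dneg if dneg else None,
    }
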