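"""Proximal operator of the weighted fused lasso penalty, entrywise in K.

For one matrix entry (i, j) the Z-update of the ADMM solves, over the
K-vector z of that entry across states,

    min_z  Σ_k (μ/2)(a_k − z_k)² + λ1·W_ij·Σ_k |z_k|·[i ≠ j]
           + λ2·W_ij·Σ_{k<k'} |z_k − z_k'|

with a_k = θ_ij^(k) + v_ij^(k).  The solution is computed exactly:

1. All-pairs fusion prox.  In the order sorted by a, the penalty
   Σ_{k<k'}|z_k − z_k'| is linear whenever z preserves that order, so the
   problem reduces to the isotonic regression of u_k = a_(k) − γ(2k − K − 1)
   (γ = λ2·W_ij/μ).  The minimizer pools sorted entries into contiguous
   blocks; all 2^(K−1) contiguous partitions are enumerated and the feasible
   one (non-decreasing block means) with the lowest squared loss is taken.
   Pooled entries share the block mean bit-for-bit, so cross-state ties are
   exact.
2. Soft-thresholding by τ = λ1·W_ij/μ (off-diagonal entries only).  The
   prox of the composite penalty decomposes as threshold-after-fuse because
   soft-thresholding weakly preserves orderings, so exact zeros are produced.

Everything is vectorized over matrix entries (axis 1); K stays small
(≤ 6 states are supported by the partition enumeration).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["fused_prox_scalar", "fused_prox_matrix", "fusion_prox"]

_MAX_K = 12  # partition enumeration is 2^(K-1); guard against abuse


def _contiguous_partitions(K: int):
    """All partitions of range(K) into contiguous blocks, fewest blocks first."""
    parts = []
    for nb in range(1, K + 1):
        for cuts in combinations(range(1, K), nb - 1):
            bounds = (0,) + cuts + (K,)
            parts.append([(bounds[b], bounds[b + 1]) for b in range(nb)])
    return parts


def fusion_prox(A: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Exact prox of the all-pairs fusion penalty, columnwise.

    Parameters
    ----------
    A : ndarray of shape (K, M)
        M independent K-vectors (columns).
    gamma : ndarray of shape (M,) or scalar
        Per-column fusion strength λ2·W/μ (≥ 0).

    Returns
    -------
    ndarray of shape (K, M)
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    K, M = A.shape
    if K == 1:
        return A.copy()
    if K > _MAX_K:
        raise ValueError(f"fusion prox supports at most {_MAX_K} states, got {K}")
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (M,))

    order = np.argsort(A, axis=0, kind="stable")
    a_sorted = np.take_along_axis(A, order, axis=0)
    ranks = np.arange(1, K + 1, dtype=float)[:, None]
    u = a_sorted - gamma[None, :] * (2.0 * ranks - K - 1.0)

    best_z = u.copy()  # 1-block-per-entry candidate overwritten below
    best_obj = np.full(M, np.inf)
    for blocks in _contiguous_partitions(K):
        z = np.empty_like(u)
        means = np.empty((len(blocks), M))
        for b, (lo, hi) in enumerate(blocks):
            m = u[lo:hi].mean(axis=0)
            means[b] = m
            z[lo:hi] = m
        feasible = np.ones(M, dtype=bool)
        for b in range(len(blocks) - 1):
            feasible &= means[b] <= means[b + 1]
        obj = ((u - z) ** 2).sum(axis=0)
        take = feasible & (obj < best_obj - 1e-15 * (1.0 + np.abs(obj)))
        if take.any():
            best_obj = np.where(take, obj, best_obj)
            best_z[:, take] = z[:, take]
    out = np.empty_like(best_z)
    np.put_along_axis(out, order, best_z, axis=0)
    return out


def _soft_threshold(z: np.ndarray, tau: np.ndarray) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - tau, 0.0)


def fused_prox_matrix(
    A: np.ndarray,
    W: np.ndarray,
    lambda1: float,
    lambda2: float,
    mu: float,
    on_diagonal: np.ndarray,
) -> np.ndarray:
    """Columnwise weighted fused lasso prox for M matrix entries at once.

    A is (K, M); W and on_diagonal are length-M (per-entry penalty weight and
    diagonal flag).  Diagonal entries skip the λ1 sparsity term — the model's
    sparsity penalty runs over i ≠ j only — but are still fused.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    K, M = A.shape
    if K < 1:
        raise ValueError("need at least one state")
    if mu <= 0:
        raise ValueError("mu must be positive")
    W = np.broadcast_to(np.asarray(W, dtype=float), (M,))
    on_diagonal = np.broadcast_to(np.asarray(on_diagonal, dtype=bool), (M,))
    z = fusion_prox(A, lambda2 * W / mu) if (lambda2 > 0 and K > 1) else A.copy()
    if lambda1 > 0:
        tau = np.where(on_diagonal, 0.0, lambda1 * W / mu)
        z = _soft_threshold(z, tau[None, :])
    return z


def fused_prox_scalar(
    a,
    W_ij: float = 1.0,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    mu: float = 1.0,
    on_diagonal: bool = False,
) -> np.ndarray:
    """Weighted fused lasso prox of a single K-vector (one matrix entry)."""
    a = np.asarray(a, dtype=float).reshape(-1, 1)
    if a.size == 0:
        raise ValueError("need at least one state")
    return fused_prox_matrix(
        a, np.array([W_ij]), lambda1, lambda2, mu, np.array([on_diagonal])
    )[:, 0]
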