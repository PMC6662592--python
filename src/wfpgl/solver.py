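"""ADMM solver for the weighted fused pathway graphical lasso.

The estimation problem couples K Gaussian log-likelihoods through a
weighted fused lasso penalty and a pathway support constraint:

    max_{Θ}  Σ_k n_k [log det Θ^(k) − tr(S^(k) Θ^(k))]
             − λ1 Σ_k Σ_{i≠j} W_ij |θ_ij^(k)|
             − λ2 Σ_{k<k'} Σ_{i,j} W_ij |θ_ij^(k) − θ_ij^(k')|
    s.t.     Θ^(k) ≻ 0,  θ_ij^(k) = 0 whenever Q_ij = 0.

Splitting Θ = Z and dualizing with scaled multipliers V = Y/μ gives the
standard three-step ADMM iteration:

* Θ-step: one block-coordinate sweep over pathways per iteration.  For
  pathway t of state k the subproblem has the closed-form solution
  Θ_t = Δ_t + U C Uᵀ, where U D Uᵀ is the eigendecomposition of
  S_t + (μ/n_k)(Δ_t − Z_t + V_t) and C_ii = (n_k/2μ)(−D_ii + √(D_ii² + 4μ/n_k)).
  Δ_t is the Schur-complement correction from the rest of the matrix.
* Z-step: the entrywise weighted fused lasso prox (exact zeros and ties).
* V-step: V ← V + Θ − Z.

μ is fixed at 1; iteration stops when the relative squared Frobenius
change Σ_k‖Θ_i − Θ_{i−1}‖²_F / Σ_k‖Θ_{i−1}‖²_F drops below tol (1e-5).
The returned sparse network estimates are the Z matrices masked by Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .core import (
    PathwayCollection,
    PenaltyConfig,
    SampleCovariance,
    SupportMask,
    WeightMatrix,
    build_support_mask,
)
from .pathways import build_block_views, compute_delta, normalize_pathways
from .prox import fused_prox_matrix

__all__ = [
    "ADMMState",
    "WfpglFit",
    "update_theta_block",
    "sweep_theta",
    "update_z",
    "update_v",
    "has_converged",
    "fit_wfpgl",
]


@dataclass
class ADMMState:
    """Per-state (Θ, Z, V) triples plus iteration bookkeeping."""

    Theta: list
    Z: list
    V: list
    iteration: int = 0
    rel_change: float = np.inf


@dataclass
class WfpglFit:
    """Result of a solver run.

    ``networks`` are the K sparse estimates (Z masked by the support mask);
    ``precisions`` are the final positive-definite Θ iterates, useful for
    likelihood-based model selection.
    """

    networks: list
    precisions: list
    converged: bool
    n_iter: int
    rel_change_trace: list = field(default_factory=list)
    config: PenaltyConfig | None = None


def update_theta_block(
    S_t: np.ndarray,
    Delta_t: np.ndarray,
    Z_t: np.ndarray,
    V_t: np.ndarray,
    n_k: int,
    mu: float,
) -> np.ndarray:
    """Closed-form pathway-block update Θ_t = Δ_t + U C Uᵀ.

    Minimizes, over T = Θ_t − Δ_t ≻ 0,
        −n_k[log det T − tr(S_t T)] + (μ/2)‖T + Δ_t − Z_t + V_t‖²_F .
    """
    for name, Mx in (("S_t", S_t), ("Delta_t", Delta_t), ("Z_t", Z_t), ("V_t", V_t)):
        if not np.allclose(Mx, Mx.T, atol=1e-8):
            raise ValueError(f"{name} must be symmetric")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if n_k < 1:
        raise ValueError("n_k must be at least 1")
    A = S_t + (mu / n_k) * (Delta_t - Z_t + V_t)
    A = (A + A.T) / 2.0
    D, U = linalg.eigh(A)
    C = (n_k / (2.0 * mu)) * (-D + np.sqrt(D**2 + 4.0 * mu / n_k))
    T = (U * C) @ U.T
    return Delta_t + (T + T.T) / 2.0


def sweep_theta(
    state: ADMMState,
    S: SampleCovariance,
    n: list,
    views: list,
    config: PenaltyConfig,
) -> ADMMState:
    """One full block-coordinate sweep over pathways, for every state.

    Pathways are processed in fixed ascending order; overlap entries are
    rewritten by every pathway containing them (sequential block-coordinate
    convention).  Entries outside the support mask are never touched and
    remain exactly zero.  Mutates and returns ``state``.
    """
    K = len(state.Theta)
    for k in range(K):
        Theta = state.Theta[k]
        for view in views:
            idx = view.inside
            Delta = compute_delta(Theta, view).Delta
            block = update_theta_block(
                S[k][np.ix_(idx, idx)],
                Delta,
                state.Z[k][np.ix_(idx, idx)],
                state.V[k][np.ix_(idx, idx)],
                n[k],
                config.mu,
            )
            Theta[np.ix_(idx, idx)] = block
    return state


def update_z(
    Theta: list,
    V: list,
    W: WeightMatrix,
    config: PenaltyConfig,
) -> list:
    """Entrywise weighted fused lasso prox of Θ + V (exactly symmetric)."""
    K = len(Theta)
    p = Theta[0].shape[0]
    for k in range(K):
        if Theta[k].shape != (p, p) or V[k].shape != (p, p):
            raise ValueError("shape mismatch between Theta and V matrices")
    iu, ju = np.triu_indices(p)
    A = np.stack([(Theta[k] + V[k])[iu, ju] for k in range(K)], axis=0)
    Zu = fused_prox_matrix(
        A,
        W.W[iu, ju],
        config.lambda1,
        config.lambda2,
        config.mu,
        on_diagonal=(iu == ju),
    )
    Z = []
    for k in range(K):
        Zk = np.zeros((p, p))
        Zk[iu, ju] = Zu[k]
        Zk[ju, iu] = Zu[k]
        Z.append(Zk)
    return Z


def update_v(V: list, Theta: list, Z: list) -> list:
    """Scaled dual ascent: V ← V + Θ − Z, per state."""
    return [Vk + Tk - Zk for Vk, Tk, Zk in zip(V, Theta, Z)]


def has_converged(Theta_prev: list, Theta_curr: list, tol: float = 1e-5) -> bool:
    """Relative squared-Frobenius-change stopping rule.

    Returns True iff Σ_k‖Θ_curr − Θ_prev‖²_F / Σ_k‖Θ_prev‖²_F < tol.
    """
    denom = sum(float(np.sum(Tp**2)) for Tp in Theta_prev)
    if denom == 0.0:
        raise ZeroDivisionError("previous iterate is all zero")
    num = sum(
        float(np.sum((Tc - Tp) ** 2)) for Tp, Tc in zip(Theta_prev, Theta_curr)
    )
    return num / denom < tol


def fit_wfpgl(
    S: SampleCovariance | list,
    n: list,
    pathways: PathwayCollection,
    W: WeightMatrix | None = None,
    config: PenaltyConfig | None = None,
) -> WfpglFit:
    """Run the full ADMM from the standard initialization Θ=I, Z=V=0.

    Parameters
    ----------
    S : SampleCovariance or list of ndarray
        K sample covariance matrices.
    n : list of int
        Per-state sample sizes.
    pathways : PathwayCollection
        Gene-index sets; normalized internally (uncovered genes become
        singleton pathways).
    W : WeightMatrix, optional
        Prior penalty weights; defaults to all ones (no prior network).
    config : PenaltyConfig, optional
        λ1, λ2, μ, max_iter, tol.
    """
    if isinstance(S, SampleCovariance):
        S_mats = S.matrices
    else:
        S_mats = list(S)
        S = SampleCovariance(matrices=S_mats)
    K = len(S_mats)
    if K != len(n):
        raise ValueError("sample-size list must have one entry per state")
    p = S_mats[0].shape[0]
    config = config or PenaltyConfig()
    if W is None:
        W = WeightMatrix(W=np.ones((p, p)), w=1.0)
    pathways = normalize_pathways(pathways, p)
    Q = build_support_mask(pathways, p)
    views = build_block_views(pathways, Q)

    state = ADMMState(
        Theta=[np.eye(p) for _ in range(K)],
        Z=[np.zeros((p, p)) for _ in range(K)],
        V=[np.zeros((p, p)) for _ in range(K)],
    )
    trace = []
    converged = False
    for it in range(1, config.max_iter + 1):
        Theta_prev = [Tk.copy() for Tk in state.Theta]
        sweep_theta(state, S, n, views, config)
        state.Z = update_z(state.Theta, state.V, W, config)
        state.V = update_v(state.V, state.Theta, state.Z)
        for k in range(K):
            if not np.all(np.isfinite(state.Theta[k])):
                raise FloatingPointError(
                    f"non-finite values in Theta[{k}] at iteration {it}"
                )
        denom = sum(float(np.sum(Tp**2)) for Tp in Theta_prev)
        num = sum(
            float(np.sum((Tc - Tp) ** 2))
            for Tp, Tc in zip(Theta_prev, state.Theta)
        )
        state.rel_change = num / denom
        state.iteration = it
        trace.append(state.rel_change)
        if state.rel_change < config.tol:
            converged = True
            break

    Qf = np.asarray(Q.Q, dtype=float)
    networks = [Zk * Qf for Zk in state.Z]
    return WfpglFit(
        networks=networks,
        precisions=[Tk.copy() for Tk in state.Theta],
        converged=converged,
        n_iter=state.iteration,
        rel_change_trace=trace,
        config=config,
    )
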