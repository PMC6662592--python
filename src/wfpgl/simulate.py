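"""Synthetic data generator for benchmarking joint network estimation.

Emulates the standard simulation design for pathway-constrained multi-state
Gaussian graphical models:

1. *Pathways*: J equal-size sets of successive gene indices, with
   neighboring pathways overlapping in n_ol genes, covering all p genes.
2. *Networks*: a scale-free (preferential-attachment) base network for
   state 1, edge weights drawn uniformly from ±[0.3, 0.6]; further states
   are derived by deleting (and, in the 3-/4-state designs, re-weighting)
   a fraction r of edges.
3. *Prior network*: a fraction η of state-1 edges, sampled uniformly, forms
   the prior interaction network G (prior edges need not be differential).
4. *Precision matrices*: Θ̃^(k) = M̃^(k) ∘ Q + (σ + b)·I, where Q is the
   pathway support mask, σ = max_k |λ_min(M̃^(k) ∘ Q)| is shared across
   states so cross-state differences come only from the edge edits, and
   b > 0 is a positive-definiteness buffer (the bare σ shift would leave
   the smallest eigenvalue at exactly zero).  Expression samples are
   zero-mean multivariate normal draws with covariance Σ = Θ̃⁻¹.

One root seed fans out to independent named sub-streams (topology, weights,
deletions, prior, sampling) so each component is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import linalg

from .core import (
    ExpressionData,
    PathwayCollection,
    PriorNetwork,
    SupportMask,
    build_support_mask,
)

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "SCENARIO_PRESETS",
    "generate_pathways",
    "generate_base_network",
    "assign_edge_weights",
    "derive_state_networks",
    "generate_prior_network",
    "build_precision",
    "sample_expression",
    "make_scenario",
]

_SUBSTREAMS = ("topology", "weights", "deletions", "prior", "sampling")


@dataclass
class ScenarioConfig:
    """Settings of one simulation scenario."""

    p: int = 400
    K: int = 2
    n: int = 100
    J: int = 10
    n_ol: int = 5
    r: float = 0.3
    eta: float = 0.8
    value_range: tuple = (0.3, 0.6)
    pd_buffer: float = 0.2
    m_attach: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.r <= 1:
            raise ValueError("edge-modification rate r must lie in [0, 1]")
        if not 0 <= self.eta <= 1:
            raise ValueError("prior rate eta must lie in [0, 1]")
        if self.pd_buffer <= 0:
            raise ValueError("pd_buffer must be positive")
        if self.K not in (2, 3, 4):
            raise ValueError("K must be 2, 3 or 4")


#: Presets mirroring the three benchmark designs.
SCENARIO_PRESETS = {
    "two_state": ScenarioConfig(p=400, K=2, n=100, J=10, n_ol=5, r=0.3),
    "three_state": ScenarioConfig(p=400, K=3, n=50, J=8, n_ol=10, r=0.1),
    "four_state": ScenarioConfig(p=200, K=4, n=50, J=5, n_ol=8, r=0.2),
}


@dataclass
class GroundTruth:
    """True networks and distributions behind a simulated dataset."""

    M: list  # K binary adjacencies
    M_weighted: list  # K real matrices with entries in ±value_range
    Theta_true: list  # K PD precision matrices
    Sigma: list  # K covariance matrices Θ̃⁻¹
    G: PriorNetwork
    pathways: PathwayCollection
    Q: SupportMask
    sigma_shift: float = 0.0


def _rngs(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


def generate_pathways(p: int, J: int, n_ol: int) -> PathwayCollection:
    """Equal-size overlapping pathways of successive gene indices.

    Size s = ceil((p + (J−1)·n_ol) / J); pathway t (1-based) starts at
    (t−1)(s − n_ol) + 1 and runs to min(start + s − 1, p), so consecutive
    pathways share exactly n_ol genes and the union covers all p.  The last
    pathway may be shorter.  Indices are stored 0-based.
    """
    if J < 1:
        raise ValueError("need at least one pathway")
    if n_ol < 0:
        raise ValueError("overlap must be non-negative")
    s = math.ceil((p + (J - 1) * n_ol) / J)
    if s <= n_ol:
        raise ValueError(
            f"infeasible pathway layout: implied size {s} <= overlap {n_ol}"
        )
    sets = []
    for t in range(J):
        start = t * (s - n_ol)  # 0-based
        stop = min(start + s, p)
        if start >= p:
            break
        sets.append(list(range(start, stop)))
    return PathwayCollection(pathways=sets, names=[f"P{t + 1}" for t in range(len(sets))])


def generate_base_network(p: int, seed, m: int = 1) -> np.ndarray:
    """Connected scale-free adjacency by preferential attachment.

    With the default m=1 new edge per incoming node the graph is a tree
    (p − 1 edges), matching the sparse regime of the benchmark designs.
    """
    if p < 2:
        raise ValueError("need at least 2 genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(p, m, seed=int(rng.integers(2**31)))
    M = nx.to_numpy_array(g, nodelist=range(p), dtype=np.int8)
    np.fill_diagonal(M, 0)
    return M


def assign_edge_weights(
    M: np.ndarray,
    value_range: tuple = (0.3, 0.6),
    seed=None,
) -> np.ndarray:
    """Replace each edge by a uniform draw from ±[lo, hi], sign fair-coin."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = value_range
    iu, ju = np.where(np.triu(M, 1) != 0)
    mags = rng.uniform(lo, hi, size=iu.size)
    signs = rng.choice([-1.0, 1.0], size=iu.size)
    Mw = np.zeros(M.shape, dtype=float)
    Mw[iu, ju] = signs * mags
    Mw[ju, iu] = Mw[iu, ju]
    return Mw


def derive_state_networks(
    M1w: np.ndarray,
    K: int,
    r: float,
    mode: str | None = None,
    seed=None,
    value_range: tuple = (0.3, 0.6),
) -> list:
    """Derive the K weighted state networks from the state-1 network.

    two_state: state 2 = state 1 with ⌊r·E⌋ uniformly chosen edges removed.
    three_state: states 1–2 as above; state 3 = state 2 with each removed
    edge independently re-weighted (new ±[lo, hi] draw) with probability ½.
    four_state: states 1–3 as three_state; state 4 = state 1 with ⌊0.2·E⌋
    uniformly chosen edges removed.  All edits are symmetric.
    """
    if mode is None:
        mode = {2: "two_state", 3: "three_state", 4: "four_state"}.get(K)
    expected_K = {"two_state": 2, "three_state": 3, "four_state": 4}.get(mode)
    if expected_K is None or expected_K != K:
        raise ValueError(f"invalid mode/K combination: mode={mode!r}, K={K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    iu, ju = np.where(np.triu(M1w, 1) != 0)
    E = iu.size
    n_rm = int(math.floor(r * E))
    removed = rng.choice(E, size=n_rm, replace=False) if n_rm else np.empty(0, int)

    M2 = M1w.copy()
    M2[iu[removed], ju[removed]] = 0.0
    M2[ju[removed], iu[removed]] = 0.0
    states = [M1w.copy(), M2]

    if mode in ("three_state", "four_state"):
        M3 = M2.copy()
        lo, hi = value_range
        for e in removed:
            if rng.random() < 0.5:
                val = rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)
                M3[iu[e], ju[e]] = val
                M3[ju[e], iu[e]] = val
        states.append(M3)

    if mode == "four_state":
        n_rm4 = int(math.floor(0.2 * E))
        rm4 = rng.choice(E, size=n_rm4, replace=False) if n_rm4 else np.empty(0, int)
        M4 = M1w.copy()
        M4[iu[rm4], ju[rm4]] = 0.0
        M4[ju[rm4], iu[rm4]] = 0.0
        states.append(M4)
    return states


def generate_prior_network(M1: np.ndarray, eta: float, seed=None) -> PriorNetwork:
    """Prior interaction network: round(η·E) edges sampled uniformly without
    replacement from the state-1 edges (not restricted to differential ones)."""
    if not 0 <= eta <= 1:
        raise ValueError("eta must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = np.where(np.triu(M1, 1) != 0)
    E = iu.size
    n_sel = int(round(eta * E))
    sel = rng.choice(E, size=n_sel, replace=False) if n_sel else np.empty(0, int)
    G = np.zeros(M1.shape, dtype=np.int8)
    G[iu[sel], ju[sel]] = 1
    G[ju[sel], iu[sel]] = 1
    return PriorNetwork(G=G)


def build_precision(
    M_weighted: list | np.ndarray,
    Q: SupportMask,
    pd_buffer: float = 0.2,
    joint_sigma: bool = True,
) -> tuple:
    """Θ̃^(k) = M̃^(k) ∘ Q + (σ + b)·I for all states.

    σ is the absolute value of the most negative eigenvalue of the masked
    weight matrices — by default the maximum over all K states, so every
    state receives the same diagonal shift and cross-state differences stem
    only from the off-diagonal edits.  The buffer b > 0 guarantees strict
    positive definiteness (λ_min(Θ̃) ≥ b).

    Returns (list of Θ̃ matrices, σ).
    """
    if pd_buffer <= 0:
        raise ValueError("pd_buffer must be positive")
    mats = [M_weighted] if isinstance(M_weighted, np.ndarray) else list(M_weighted)
    Qf = np.asarray(Q.Q, dtype=float)
    masked = []
    for Mw in mats:
        A = Mw * Qf
        np.fill_diagonal(A, 0.0)
        masked.append(A)
    sigmas = [abs(min(linalg.eigvalsh(A).min(), 0.0)) for A in masked]
    if joint_sigma:
        sigmas = [max(sigmas)] * len(masked)
    Thetas = [A + (s + pd_buffer) * np.eye(A.shape[0]) for A, s in zip(masked, sigmas)]
    return Thetas, max(sigmas)


def sample_expression(Theta_true: np.ndarray, n: int, seed=None) -> np.ndarray:
    """n zero-mean multivariate normal draws with covariance Θ̃⁻¹ (p × n)."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        L_theta = linalg.cholesky(Theta_true, lower=True)
    except linalg.LinAlgError as e:
        raise ValueError(f"precision matrix is not positive definite: {e}") from e
    Sigma = linalg.cho_solve((L_theta, True), np.eye(Theta_true.shape[0]))
    Sigma = (Sigma + Sigma.T) / 2.0
    L = linalg.cholesky(Sigma, lower=True)
    return L @ rng.standard_normal((Theta_true.shape[0], n))


def make_scenario(config: ScenarioConfig) -> tuple:
    """End-to-end simulation: returns (ExpressionData, GroundTruth)."""
    rngs = _rngs(config.seed)
    pathways = generate_pathways(config.p, config.J, config.n_ol)
    Q = build_support_mask(pathways, config.p)
    M1 = generate_base_network(config.p, rngs["topology"], m=config.m_attach)
    M1w = assign_edge_weights(M1, config.value_range, rngs["weights"])
    states = derive_state_networks(
        M1w, config.K, config.r, seed=rngs["deletions"], value_range=config.value_range
    )
    G = generate_prior_network(M1, config.eta, rngs["prior"])
    Thetas, sigma = build_precision(states, Q, pd_buffer=config.pd_buffer)
    Sigmas = [linalg.inv(T) for T in Thetas]
    X = [sample_expression(T, config.n, rngs["sampling"]) for T in Thetas]
    width = len(str(config.p))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.p)]
    data = ExpressionData(
        states=[f"state_{k + 1}" for k in range(config.K)],
        matrices=X,
        gene_ids=gene_ids,
    )
    truth = GroundTruth(
        M=[(np.abs(Mw) > 0).astype(np.int8) for Mw in states],
        M_weighted=states,
        Theta_true=Thetas,
        Sigma=Sigmas,
        G=G,
        pathways=pathways,
        Q=Q,
        sigma_shift=sigma,
    )
    return data, truth


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    """A named preset with optional field overrides (e.g. p or seed)."""
    if name not in SCENARIO_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(SCENARIO_PRESETS)}")
    return replace(SCENARIO_PRESETS[name], **overrides)
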