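"""Core domain containers and the basic matrix constructions.

The model works on K groups of expression samples measured over a shared
set of p genes.  Each group (biological state) carries its own sample
covariance S^(k); structural prior knowledge enters through two matrices:

* a binary support mask Q derived from a pathway collection — θ_ij is
  constrained to zero unless genes i and j co-occur in some pathway;
* a penalty weight matrix W derived from a prior interaction network G —
  gene pairs with a known interaction are penalized by w ∈ [0, 1] instead
  of 1, so those edges (and their cross-state differences) survive
  shrinkage more easily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionData",
    "SampleCovariance",
    "PathwayCollection",
    "SupportMask",
    "PriorNetwork",
    "WeightMatrix",
    "PenaltyConfig",
    "compute_sample_covariance",
    "build_support_mask",
    "build_weight_matrix",
]


@dataclass
class ExpressionData:
    """Per-state gene × sample expression matrices with a shared gene index.

    Attributes
    ----------
    states : list of str
        Ordered state labels, length K.
    matrices : list of ndarray
        One (p, n_k) matrix per state, rows aligned to ``gene_ids``.
    gene_ids : list of str
        Length-p gene identifiers shared across states.
    """

    states: list
    matrices: list
    gene_ids: list

    def __post_init__(self):
        if len(self.states) != len(self.matrices):
            raise ValueError("states and matrices must have equal length")
        if len(self.states) < 1:
            raise ValueError("need at least one state")
        p = len(self.gene_ids)
        for lab, X in zip(self.states, self.matrices):
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != p:
                raise ValueError(
                    f"state {lab!r}: expected {p} gene rows, got shape {X.shape}"
                )
            if X.shape[1] < 2:
                raise ValueError(f"state {lab!r}: need at least 2 samples")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def sample_sizes(self) -> list:
        return [X.shape[1] for X in self.matrices]


@dataclass
class SampleCovariance:
    """K symmetric PSD p × p sample covariance matrices."""

    matrices: list

    def __post_init__(self):
        for S in self.matrices:
            if not np.allclose(S, S.T, atol=1e-12):
                raise ValueError("sample covariance must be symmetric")

    def __len__(self):
        return len(self.matrices)

    def __getitem__(self, k):
        return self.matrices[k]


@dataclass
class PathwayCollection:
    """A list of gene-index sets P_t (0-based indices into the gene list)."""

    pathways: list
    names: list | None = None

    def __post_init__(self):
        self.pathways = [sorted(set(int(i) for i in P)) for P in self.pathways]
        for t, P in enumerate(self.pathways):
            if len(P) == 0:
                raise ValueError(f"pathway {t} is empty")
            if min(P) < 0:
                raise ValueError(f"pathway {t} contains a negative index")
        if self.names is not None and len(self.names) != len(self.pathways):
            raise ValueError("names length must match pathway count")

    def __len__(self):
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def covers(self, p: int) -> bool:
        union = set()
        for P in self.pathways:
            union.update(P)
        return union == set(range(p))


@dataclass
class SupportMask:
    """Binary symmetric p × p mask of pathway-allowed edges; diagonal all 1."""

    Q: np.ndarray

    def __post_init__(self):
        Q = np.asarray(self.Q)
        if not np.array_equal(Q, Q.T):
            raise ValueError("support mask must be symmetric")
        if not np.all(np.diag(Q) == 1):
            raise ValueError("support mask diagonal must be all ones")
        self.Q = Q.astype(np.int8)

    @property
    def p(self) -> int:
        return self.Q.shape[0]


@dataclass
class PriorNetwork:
    """Binary symmetric adjacency of known gene interactions, zero diagonal."""

    G: np.ndarray

    def __post_init__(self):
        G = np.asarray(self.G)
        if not np.array_equal(G, G.T):
            raise ValueError("prior network adjacency must be symmetric")
        if np.any(np.diag(G) != 0):
            raise ValueError("prior network must have zero diagonal")
        self.G = G.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.G, 1).sum())


@dataclass
class WeightMatrix:
    """Penalty weights: W_ij = w on prior edges, 1 elsewhere (incl. diagonal)."""

    W: np.ndarray
    w: float = 1.0


@dataclass
class PenaltyConfig:
    """Tuning and solver parameters.

    lambda1 controls sparsity of the individual networks, lambda2 the
    sparsity of cross-state differences; mu is the ADMM penalty (fixed at 1
    throughout a run); tol is the relative squared-Frobenius-change stopping
    threshold.
    """

    lambda1: float = 0.1
    lambda2: float = 0.01
    mu: float = 1.0
    max_iter: int = 500
    tol: float = 1e-5

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty parameters must be non-negative")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


def compute_sample_covariance(
    X: np.ndarray,
    standardize: bool = False,
    ddof: int = 0,
) -> np.ndarray:
    """Sample covariance of a gene × sample matrix.

    Rows (genes) are centered; with ``standardize`` they are also scaled to
    unit standard deviation first, so the output is a correlation-like
    matrix with unit diagonal.  The default denominator is n (maximum
    likelihood); ``ddof=1`` gives the unbiased 1/(n−1) version.

    Parameters
    ----------
    X : ndarray of shape (p, n)
        Expression matrix, genes in rows.
    standardize : bool
        Scale each gene to unit standard deviation after centering.
    ddof : int
        Delta degrees of freedom in the denominator (0 → 1/n, 1 → 1/(n−1)).

    Returns
    -------
    ndarray of shape (p, p), symmetric PSD.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D gene × sample matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    p, n = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    Xc = X - X.mean(axis=1, keepdims=True)
    if standardize:
        sd = np.sqrt((Xc**2).mean(axis=1))
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance gene(s) at row(s) {zero.tolist()} cannot be standardized"
            )
        Xc = Xc / sd[:, None]
    S = (Xc @ Xc.T) / (n - ddof)
    return (S + S.T) / 2.0


def build_support_mask(pathways: PathwayCollection, p: int) -> SupportMask:
    """Binary mask Q with Q_ij = 1 iff i = j or i, j share a pathway."""
    Q = np.eye(p, dtype=np.int8)
    for t, P in enumerate(pathways):
        idx = np.asarray(P, dtype=int)
        if idx.size and idx.max() >= p:
            raise ValueError(f"pathway {t} contains index {idx.max()} >= p={p}")
        Q[np.ix_(idx, idx)] = 1
    return SupportMask(Q)


def build_weight_matrix(G: PriorNetwork, w: float) -> WeightMatrix:
    """Penalty weights from the prior network: w on known edges, 1 elsewhere."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"prior weight w must lie in [0, 1], got {w}")
    W = np.ones_like(G.G, dtype=float)
    W[G.G == 1] = w
    np.fill_diagonal(W, 1.0)
    return WeightMatrix(W=W, w=w)
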