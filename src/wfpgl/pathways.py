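"""Pathway-separable machinery.

The log-likelihood of a pathway-constrained Gaussian graphical model is
pathway separable: with the precision matrix permuted so that one pathway's
genes come first, the determinant factorizes as

    det(Θ) = det(Θ_outside) · det(Θ_pathway − Δ),

where Δ = B · Θ_outside⁻¹ · Bᵀ is the Schur-complement correction and B is
the pathway × outside block of Θ.  Because the support constraint zeroes
every entry between a gene found *only* in this pathway and any outside
gene, Δ is nonzero only on the rows/columns of genes the pathway shares
with the rest of the collection.  The block-coordinate Θ-update therefore
needs only Δ from the rest of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import PathwayCollection, SupportMask

__all__ = [
    "PathwayBlockView",
    "DeltaBlock",
    "normalize_pathways",
    "build_block_views",
    "compute_delta",
]


@dataclass
class PathwayBlockView:
    """Index bookkeeping for one pathway's block update.

    ``inside`` is the sorted gene-index list of the pathway, ``outside`` its
    complement, and ``overlap`` the positions *within ``inside``* of genes
    that may carry an edge to some outside gene (i.e. co-occur with an
    outside gene in another pathway).
    """

    t: int
    inside: np.ndarray
    outside: np.ndarray
    overlap: np.ndarray  # positions into `inside`

    def __post_init__(self):
        self.inside = np.asarray(self.inside, dtype=int)
        self.outside = np.asarray(self.outside, dtype=int)
        self.overlap = np.asarray(self.overlap, dtype=int)


@dataclass
class DeltaBlock:
    """Schur-complement correction Δ_t for one pathway block; symmetric PSD,
    nonzero only on the overlap rows/columns."""

    Delta: np.ndarray


def normalize_pathways(pathways: PathwayCollection, p: int) -> PathwayCollection:
    """Canonicalize a pathway collection over p genes.

    Deduplicates identical sets, keeps the original ordering of first
    occurrence, and appends every uncovered gene as a singleton pathway so
    the union covers all genes (a singleton allows only its own diagonal
    entry).
    """
    seen = set()
    out, names = [], []
    in_names = pathways.names or [f"pathway_{t}" for t in range(len(pathways))]
    for name, P in zip(in_names, pathways):
        key = tuple(P)
        if max(P) >= p:
            raise ValueError(f"pathway {name!r} contains index {max(P)} >= p={p}")
        if key in seen:
            continue
        seen.add(key)
        out.append(list(P))
        names.append(name)
    covered = set()
    for P in out:
        covered.update(P)
    if not out:
        warnings.warn("empty pathway collection: every gene becomes a singleton pathway")
    for g in range(p):
        if g not in covered:
            out.append([g])
            names.append(f"singleton_{g}")
    return PathwayCollection(pathways=out, names=names)


def build_block_views(pathways: PathwayCollection, Q: SupportMask) -> list:
    """One PathwayBlockView per pathway, in fixed ascending pathway order."""
    p = Q.p
    all_idx = np.arange(p)
    views = []
    Qm = np.asarray(Q.Q, dtype=bool)
    for t, P in enumerate(pathways):
        inside = np.asarray(P, dtype=int)
        mask = np.ones(p, dtype=bool)
        mask[inside] = False
        outside = all_idx[mask]
        if outside.size:
            # overlap genes: allowed (by Q) to touch at least one outside gene
            touches = Qm[np.ix_(inside, outside)].any(axis=1)
            overlap = np.flatnonzero(touches)
        else:
            overlap = np.empty(0, dtype=int)
        views.append(PathwayBlockView(t=t, inside=inside, outside=outside, overlap=overlap))
    return views


def compute_delta(Theta: np.ndarray, view: PathwayBlockView) -> DeltaBlock:
    """Schur-complement correction Δ_t = B · Θ_outside⁻¹ · Bᵀ.

    B is the inside × outside block of Θ; only the overlap rows of B can be
    nonzero, so the linear solve is restricted to overlap × outside size.
    The outside block is factorized by Cholesky — no explicit inversion.
    """
    p_t = view.inside.size
    Delta = np.zeros((p_t, p_t))
    if view.outside.size == 0 or view.overlap.size == 0:
        return DeltaBlock(Delta=Delta)
    rows = view.inside[view.overlap]
    B = Theta[np.ix_(rows, view.outside)]
    if not B.any():
        return DeltaBlock(Delta=Delta)
    A = Theta[np.ix_(view.outside, view.outside)]
    try:
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
    except linalg.LinAlgError as e:
        raise linalg.LinAlgError(
            f"outside block of pathway {view.t} is singular/not PD: {e}"
        ) from e
    # Δ_ov = B A⁻¹ Bᵀ, symmetrized against roundoff
    D_ov = B @ linalg.cho_solve(cho, B.T, check_finite=False)
    D_ov = (D_ov + D_ov.T) / 2.0
    Delta[np.ix_(view.overlap, view.overlap)] = D_ov
    return DeltaBlock(Delta=Delta)
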