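"""Accuracy metrics, AIC model selection, and hub-gene ranking.

Network recovery is scored over unordered gene pairs i < j:

    TPR  = #{(k, i<j): θ̂_ij^(k) ≠ 0 and θ_ij^(k) ≠ 0} / #{(k, i<j): θ_ij^(k) ≠ 0}
    FPR  = #{(k, i<j): θ̂_ij^(k) ≠ 0 and θ_ij^(k) = 0} / #{(k, i<j): θ_ij^(k) = 0}

and differential recovery over state pairs k < k′:

    TPDR = #{(k<k′, i<j): θ̂ differs and θ differs} / #{(k<k′, i<j): θ differs}
    FPDR = #{(k<k′, i<j): θ̂ differs and θ equal}  / #{(k<k′, i<j): θ equal}

"differs" means |difference| > tol; the solver's proximal Z-update produces
exact zeros and exact cross-state ties, so any tiny tolerance gives the
same answer on its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PathwayCollection, PenaltyConfig, SampleCovariance, WeightMatrix

__all__ = [
    "MetricsReport",
    "AicTable",
    "binarize",
    "compute_metrics",
    "differential_edges",
    "compute_aic",
    "select_model",
    "hub_ranking",
]


@dataclass
class MetricsReport:
    tpr: float
    fpr: float
    tpdr: float | None
    fpdr: float | None
    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "tpr": self.tpr,
            "fpr": self.fpr,
            "tpdr": self.tpdr,
            "fpdr": self.fpdr,
            "counts": self.counts,
        }


@dataclass
class AicTable:
    """AIC values over a (λ1, λ2) grid with the deterministic argmin."""

    entries: list  # (lambda1, lambda2, aic)
    argmin: tuple  # (lambda1, lambda2)


def binarize(network: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Binary adjacency: 1 where |value| > tol."""
    return (np.abs(np.asarray(network)) > tol).astype(np.int8)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(
    truth: list,
    estimates: list,
    tol: float = 1e-8,
    differential: bool = True,
) -> MetricsReport:
    """TPR/FPR (and TPDR/FPDR for K ≥ 2) of estimated networks vs truth."""
    K = len(truth)
    if K != len(estimates):
        raise ValueError("truth and estimates must have the same number of states")
    p = truth[0].shape[0]
    iu, ju = np.triu_indices(p, k=1)
    t_nz = np.stack([np.abs(T[iu, ju]) > tol for T in truth])
    e_nz = np.stack([np.abs(E[iu, ju]) > tol for E in estimates])

    tp = int((t_nz & e_nz).sum())
    pos = int(t_nz.sum())
    fp = int((~t_nz & e_nz).sum())
    neg = int((~t_nz).sum())
    counts = {"tp": tp, "pos": pos, "fp": fp, "neg": neg}

    tpdr = fpdr = None
    if differential:
        if K < 2:
            raise ValueError("differential metrics require at least two states")
        tv = np.stack([T[iu, ju] for T in truth])
        ev = np.stack([E[iu, ju] for E in estimates])
        dtp = dpos = dfp = dneg = 0
        for k in range(K):
            for k2 in range(k + 1, K):
                t_diff = np.abs(tv[k] - tv[k2]) > tol
                e_diff = np.abs(ev[k] - ev[k2]) > tol
                dtp += int((t_diff & e_diff).sum())
                dpos += int(t_diff.sum())
                dfp += int((~t_diff & e_diff).sum())
                dneg += int((~t_diff).sum())
        counts.update({"dtp": dtp, "dpos": dpos, "dfp": dfp, "dneg": dneg})
        tpdr = _ratio(dtp, dpos)
        fpdr = _ratio(dfp, dneg)

    return MetricsReport(
        tpr=_ratio(tp, pos),
        fpr=_ratio(fp, neg),
        tpdr=tpdr,
        fpdr=fpdr,
        counts=counts,
    )


def differential_edges(
    est_k: np.ndarray, est_k2: np.ndarray, tol: float = 1e-8
) -> list:
    """Pairs i < j whose entries differ between two estimates, with the
    signed difference est_k − est_k2."""
    if est_k.shape != est_k2.shape:
        raise ValueError("estimates must have the same shape")
    D = est_k - est_k2
    iu, ju = np.triu_indices(D.shape[0], k=1)
    keep = np.abs(D[iu, ju]) > tol
    return [(int(i), int(j), float(D[i, j])) for i, j in zip(iu[keep], ju[keep])]


def compute_aic(
    S: SampleCovariance | list,
    estimates: list,
    n: list,
    supports: list | None = None,
    tol: float = 1e-8,
) -> float:
    """AIC(λ1, λ2) = Σ_k [n_k·tr(S^(k)Θ̂^(k)) − n_k·log det Θ̂^(k) + 2·n_e^(k)].

    n_e^(k) is the number of nonzero upper-triangle off-diagonal entries,
    counted on ``supports`` when given (typically the sparse Z estimates)
    and on ``estimates`` otherwise.  Returns +inf if any estimate is not
    positive definite.
    """
    S_mats = S.matrices if isinstance(S, SampleCovariance) else list(S)
    if supports is None:
        supports = estimates
    total = 0.0
    for Sk, Tk, Pk, nk in zip(S_mats, estimates, supports, n):
        sign, logdet = np.linalg.slogdet(Tk)
        if sign <= 0 or np.linalg.eigvalsh(Tk).min() <= 0:
            return np.inf
        n_e = int((np.abs(np.triu(Pk, 1)) > tol).sum())
        total += nk * float(np.trace(Sk @ Tk)) - nk * logdet + 2 * n_e
    return total


def select_model(
    S: SampleCovariance | list,
    n: list,
    pathways: PathwayCollection,
    W: WeightMatrix | None,
    lambda1_grid,
    lambda2_grid,
    config: PenaltyConfig | None = None,
):
    """Fit every (λ1, λ2) pair and return (AicTable, best WfpglFit).

    AIC is evaluated on the PD Θ iterates with the sparsity pattern taken
    from the Z estimates.  Ties break toward the smallest λ1, then λ2.
    Failed fits are recorded with AIC = +inf and excluded from the argmin.
    """
    from dataclasses import replace as _replace

    from .solver import fit_wfpgl

    l1s = sorted(set(float(v) for v in lambda1_grid))
    l2s = sorted(set(float(v) for v in lambda2_grid))
    if not l1s or not l2s:
        raise ValueError("tuning grids must be non-empty")
    base = config or PenaltyConfig()
    entries = []
    best = None
    best_key = None
    for l1 in l1s:
        for l2 in l2s:
            cfg = _replace(base, lambda1=l1, lambda2=l2)
            try:
                fit = fit_wfpgl(S, n, pathways, W, cfg)
                aic = compute_aic(S, fit.precisions, n, supports=fit.networks)
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                fit, aic = None, np.inf
            entries.append((l1, l2, aic))
            if fit is not None and (best_key is None or aic < best_key):
                best_key = aic
                best = (l1, l2, fit)
    if best is None:
        raise RuntimeError("all grid fits failed")
    return AicTable(entries=entries, argmin=(best[0], best[1])), best[2]


def hub_ranking(network: np.ndarray, gene_ids: list, top_m: int = 10) -> list:
    """Genes ranked by degree (descending, ties lexicographic by gene ID).

    Returns the top_m (gene_id, degree) pairs of the binarized network;
    diagonal entries are ignored.
    """
    A = binarize(network)
    np.fill_diagonal(A, 0)
    deg = A.sum(axis=0)
    order = sorted(range(len(gene_ids)), key=lambda i: (-int(deg[i]), gene_ids[i]))
    return [(gene_ids[i], int(deg[i])) for i in order[:top_m]]
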