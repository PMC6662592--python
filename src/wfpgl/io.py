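"""Readers and writers for the plain-text formats the tool touches.

Expression tables are TSV/CSV with gene identifiers in the first column and
samples in the remaining columns (one file per state).  Pathways use the
standard GMT dialect (name, description, tab-separated gene symbols);
prior networks are two-column undirected edge lists (SIF's three-column
``gene  interaction  gene`` form is also accepted).  All writes are atomic
(temp file then rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionData, PathwayCollection, PriorNetwork

logger = logging.getLogger("wfpgl")

__all__ = [
    "read_expression_tables",
    "read_gmt",
    "pathways_from_symbols",
    "read_edge_list",
    "write_networks",
    "write_report",
    "write_expression",
    "write_gmt",
    "write_edge_list",
]


def _atomic_write(path, text: str):
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
    df.index = df.index.astype(str)
    # duplicate gene rows are merged by their average
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    return df.astype(float)


def read_expression_tables(paths, states=None) -> ExpressionData:
    """Load one expression table per state into a shared-gene-index bundle.

    Gene sets are harmonized to their intersection across states, keeping
    the gene order of the first file; dropped genes are logged.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("need at least one expression file")
    if states is None:
        states = [p.stem for p in paths]
    tables = [_read_table(p) for p in paths]
    common = set(tables[0].index)
    for df in tables[1:]:
        common &= set(df.index)
    if not common:
        raise ValueError("expression files share no genes")
    gene_ids = [g for g in tables[0].index if g in common]
    dropped = sum(len(df) - len(gene_ids) for df in tables)
    if dropped:
        logger.warning("dropped %d gene rows outside the shared gene set", dropped)
    matrices = [df.loc[gene_ids].to_numpy(dtype=float) for df in tables]
    return ExpressionData(states=list(states), matrices=matrices, gene_ids=gene_ids)


def read_gmt(path) -> list:
    """Parse a GMT file into (name, description, [gene symbols]) tuples."""
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description and genes")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{ln}: gene set {parts[0]!r} is empty")
            sets.append((parts[0], parts[1], genes))
    return sets


def pathways_from_symbols(gene_sets, gene_ids) -> PathwayCollection:
    """Map symbol-based gene sets onto expression gene indices.

    Symbols absent from the expression index are dropped (count logged);
    sets left empty after the drop are discarded.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    pathways, names = [], []
    missing = 0
    for entry in gene_sets:
        name, genes = (entry[0], entry[-1]) if len(entry) == 3 else entry
        idx = [index[g] for g in genes if g in index]
        missing += len(genes) - len(idx)
        if idx:
            pathways.append(sorted(set(idx)))
            names.append(name)
    if missing:
        logger.warning("dropped %d pathway genes absent from the expression index", missing)
    if not pathways:
        raise ValueError("no pathway gene overlaps the expression gene index")
    return PathwayCollection(pathways=pathways, names=names)


def read_edge_list(path, gene_ids) -> PriorNetwork:
    """Undirected prior network from a two-column TSV (or three-column SIF)
    edge list; duplicates and reversed duplicates collapse to one edge."""
    index = {g: i for i, g in enumerate(gene_ids)}
    G = np.zeros((len(gene_ids), len(gene_ids)), dtype=np.int8)
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 3:  # SIF: source interaction target
                a, b = parts[0], parts[2]
            elif len(parts) == 2:
                a, b = parts
            else:
                raise ValueError(f"{path}:{ln}: expected 2 (edge list) or 3 (SIF) columns")
            if a == b:
                continue
            if a in index and b in index:
                G[index[a], index[b]] = 1
                G[index[b], index[a]] = 1
            else:
                skipped += 1
    if skipped:
        logger.warning("skipped %d prior edges with genes absent from the index", skipped)
    return PriorNetwork(G=G)


def _edges_text(M: np.ndarray, gene_ids, tol: float = 0.0) -> str:
    lines = ["gene_i\tgene_j\tweight"]
    iu, ju = np.triu_indices(M.shape[0], k=1)
    for i, j in zip(iu, ju):
        v = M[i, j]
        if abs(v) > tol:
            lines.append(f"{gene_ids[i]}\t{gene_ids[j]}\t{v:.10g}")
    return "\n".join(lines) + "\n"


def write_networks(fit, gene_ids, out_dir, states=None):
    """Per-state edge-list TSVs plus per-pair differential edge lists.

    Exact zeros are omitted; rows are sorted by gene index.  Returns the
    list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    networks = fit.networks if hasattr(fit, "networks") else list(fit)
    K = len(networks)
    states = states or [f"state_{k + 1}" for k in range(K)]
    written = []
    for k, Zk in enumerate(networks):
        path = out_dir / f"network_{states[k]}.tsv"
        _atomic_write(path, _edges_text(Zk, gene_ids))
        written.append(path)
    for k in range(K):
        for k2 in range(k + 1, K):
            D = networks[k] - networks[k2]
            path = out_dir / f"differential_{states[k]}_vs_{states[k2]}.tsv"
            _atomic_write(path, _edges_text(D, gene_ids, tol=1e-12))
            written.append(path)
    return written


def write_report(report: dict, path):
    """Atomic JSON dump of a run report."""
    _atomic_write(path, json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_expression(data: ExpressionData, out_dir) -> list:
    """One TSV per state: gene column plus sample columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for lab, X in zip(data.states, data.matrices):
        df = pd.DataFrame(
            X,
            index=pd.Index(data.gene_ids, name="gene"),
            columns=[f"s{j + 1}" for j in range(X.shape[1])],
        )
        path = out_dir / f"expression_{lab}.tsv"
        _atomic_write(path, df.to_csv(sep="\t", float_format="%.10g"))
        written.append(path)
    return written


def write_gmt(pathways: PathwayCollection, gene_ids, path):
    names = pathways.names or [f"P{t + 1}" for t in range(len(pathways))]
    lines = []
    for name, P in zip(names, pathways):
        genes = "\t".join(gene_ids[i] for i in P)
        lines.append(f"{name}\tna\t{genes}")
    _atomic_write(path, "\n".join(lines) + "\n")


def write_edge_list(M: np.ndarray, gene_ids, path):
    """Two-column undirected edge list of the nonzero upper triangle."""
    lines = []
    iu, ju = np.triu_indices(M.shape[0], k=1)
    for i, j in zip(iu, ju):
        if M[i, j] != 0:
            lines.append(f"{gene_ids[i]}\t{gene_ids[j]}")
    _atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))
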