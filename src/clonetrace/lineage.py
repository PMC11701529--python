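"""Lineage-relationship inference from shared barcode signatures.

Two cell types that arise from a common pool of progenitor clones share
barcodes, so their per-clone count vectors ("barcode signatures") correlate.
Spearman correlation over clones, computed for every cell-type pair, gives a
lineage-coupling matrix; average-linkage clustering of 1 - rho yields a
lineage dendrogram (emitted as Newick).

Signatures are raw per-clone counts by default (ranks make raw vs normalized
nearly equivalent); ``use="fate_map"`` switches to the row-normalized fate
map.  For each pair, clones with zero cells in BOTH members are excluded
(they carry no ordering information); ``universe="global"`` keeps every
clone instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance
from scipy.stats import rankdata

from .io import CloneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LineageCorrelation",
    "spearman_rho",
    "lineage_relationship",
    "lineage_tree",
]


@dataclass
class LineageCorrelation:
    """Symmetric Spearman-rho matrix over cell types."""

    labels: list[str]
    rho: np.ndarray
    n_clones_used: int

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.labels)
        if self.rho.shape != (n, n):
            raise ValueError("rho shape inconsistent with labels")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12, equal_nan=True):
            raise ValueError("rho must be symmetric")
        if np.nanmax(np.abs(self.rho)) > 1 + 1e-9:
            raise ValueError("rho values must lie in [-1, 1]")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman correlation (Pearson on average ranks).

    A constant vector has no rank ordering; the correlation is defined as 0
    (uninformative) with a logged warning rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("vectors must be 1-D with length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        logger.warning("constant vector in spearman_rho; returning 0")
        return 0.0
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


def lineage_relationship(
    clone_matrix: CloneMatrix,
    subset: Sequence[str] | None = None,
    use: str = "counts",
    universe: str = "pairwise",
) -> LineageCorrelation:
    """Spearman-rho lineage-coupling matrix between cell types."""
    labels = list(subset) if subset is not None else list(clone_matrix.column_labels)
    unknown = set(labels) - set(clone_matrix.column_labels)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    col_index = {lab: j for j, lab in enumerate(clone_matrix.column_labels)}
    cols = [col_index[lab] for lab in labels]
    data = clone_matrix.counts[:, cols].astype(float)
    if use == "fate_map":
        data = data / clone_matrix.counts.sum(axis=1)[:, None]
    elif use != "counts":
        raise ValueError(f"unknown use {use!r}")
    usable = data.sum(axis=1) > 0
    data = data[usable]
    n_used = int(usable.sum())
    if n_used < 3:
        raise ValueError(f"only {n_used} usable clones; need >= 3")
    n = len(labels)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if universe == "pairwise":
                mask = (data[:, i] > 0) | (data[:, j] > 0)
            elif universe == "global":
                mask = np.ones(data.shape[0], dtype=bool)
            else:
                raise ValueError(f"unknown universe {universe!r}")
            if mask.sum() < 3:
                logger.warning(
                    "pair (%s, %s): only %d supporting clones; rho set to 0",
                    labels[i], labels[j], int(mask.sum()),
                )
                r = 0.0
            else:
                r = spearman_rho(data[mask, i], data[mask, j])
            rho[i, j] = rho[j, i] = r
    return LineageCorrelation(labels, rho, n_used)


def lineage_tree(corr: LineageCorrelation, method: str = "average") -> str:
    """Hierarchical lineage dendrogram as a Newick string.

    Cell types are clustered on d = 1 - rho with the given linkage
    (average by default).  The tree is ultrametric: each child branch length
    is half the difference between the parent and child merge heights, so
    the leaf-to-leaf path length equals the merge distance.
    """
    if len(corr.labels) < 2:
        raise ValueError("need >= 2 labels to build a tree")
    if not np.isfinite(corr.rho).all():
        raise ValueError("non-finite correlation values")
    dist = 1.0 - corr.rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    linkage = scipy.cluster.hierarchy.linkage(condensed, method=method)
    root = scipy.cluster.hierarchy.to_tree(linkage)

    def newick(node) -> str:
        if node.is_leaf():
            return corr.labels[node.id]
        left = newick(node.left)
        right = newick(node.right)
        bl_left = (node.dist - node.left.dist) / 2.0
        bl_right = (node.dist - node.right.dist) / 2.0
        return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"

    return newick(root) + ";"
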