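"""Barcode resolution, high-confidence clone filtering and quality metrics.

A single-cell lineage-tracing readout pairs each cell index with one or more
barcode sequences.  Ideally one cell carries one barcode, but sequencing
error and ambient contamination produce multi-barcode cells.  Source studies
resolve these with study-specific rules; here a single parameterized
dominance policy is used: a multi-barcode cell is kept iff its top barcode
count is at least ``min_dominance`` times the runner-up (default 2x) and at
least ``min_count``.  Ties fail dominance and the cell is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BarcodeAssignment, CellRecord, CloneMatrix

__all__ = [
    "ResolutionPolicy",
    "QualitySummary",
    "resolve_barcodes",
    "filter_high_confidence",
    "quality_summary",
    "clone_sizes",
    "barcode_statistics",
]


@dataclass(frozen=True)
class ResolutionPolicy:
    """Dominance rule for multi-barcode cells.

    min_dominance
        Required ratio of top to second barcode count (>= 1).
    min_count
        Minimum count for the winning barcode.
    """

    min_dominance: float = 2.0
    min_count: int = 1

    def __post_init__(self) -> None:
        if self.min_dominance < 1:
            raise ValueError("min_dominance must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass(frozen=True)
class QualitySummary:
    """Dataset-level barcode quality: detection rate and barcode diversity."""

    n_cells: int
    n_barcoded_cells: int
    n_unique_barcodes: int
    detection_rate: float


def resolve_barcodes(
    assignments: Iterable[BarcodeAssignment],
    policy: ResolutionPolicy = ResolutionPolicy(),
) -> dict[str, str]:
    """Resolve each cell to a unique barcode under the dominance policy.

    Returns a ``cell_id -> barcode_id`` map covering only the kept cells.
    Resolution is per-cell, hence idempotent and independent of input order.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no barcode assignments supplied")
    resolved: dict[str, str] = {}
    for a in assignments:
        # deterministic winner: highest count, then lexicographic barcode id
        entries = sorted(a.entries, key=lambda e: (-e[1], e[0]))
        top_bc, top_count = entries[0]
        if top_count < policy.min_count:
            continue
        if len(entries) > 1:
            second_count = entries[1][1]
            if top_count < policy.min_dominance * second_count:
                continue
        resolved[a.cell_id] = top_bc
    return resolved


def filter_high_confidence(
    clone_matrix: CloneMatrix,
    initial_counts: Mapping[str, int] | None = None,
    max_initial_cells: int = 1,
) -> CloneMatrix:
    """Drop barcodes that labelled more than one cell at the barcoding stage.

    A barcode integrated into several progenitors does not mark a single
    clone.  Filtering requires explicit initial-stage evidence
    (``initial_counts``); without it the matrix is returned unchanged — no
    heuristic inference from late time points is attempted.
    """
    if initial_counts is None:
        return clone_matrix
    unknown = set(initial_counts) - set(clone_matrix.clone_ids)
    if unknown:
        raise ValueError(f"initial_counts has unknown clone id(s): {sorted(unknown)[:5]}")
    missing = set(clone_matrix.clone_ids) - set(initial_counts)
    if missing:
        raise ValueError(
            f"initial_counts missing clone id(s): {sorted(missing)[:5]}"
        )
    keep = [c for c in clone_matrix.clone_ids if initial_counts[c] <= max_initial_cells]
    if not keep:
        raise ValueError("no clone passes the high-confidence filter")
    return clone_matrix.select_clones(keep)


def quality_summary(
    cells: Sequence[CellRecord], resolved: Mapping[str, str]
) -> QualitySummary:
    """Compute detection rate and unique-barcode number for a dataset."""
    if len(cells) == 0:
        raise ValueError("no cells supplied")
    cell_ids = {c.cell_id for c in cells}
    stray = set(resolved) - cell_ids
    if stray:
        raise ValueError(f"resolved map has unknown cell id(s): {sorted(stray)[:5]}")
    n_barcoded = len(resolved)
    return QualitySummary(
        n_cells=len(cells),
        n_barcoded_cells=n_barcoded,
        n_unique_barcodes=len(set(resolved.values())),
        detection_rate=n_barcoded / len(cells),
    )


def clone_sizes(clone_matrix: CloneMatrix) -> pd.DataFrame:
    """Per-clone size table, descending by size.

    Clone size is the number of cells carrying the clone's barcode (row sum);
    ``n_cell_types`` counts the columns the clone occupies.  Size ties break
    lexicographically on clone id.
    """
    sizes = clone_matrix.counts.sum(axis=1)
    n_types = (clone_matrix.counts > 0).sum(axis=1)
    df = pd.DataFrame(
        {
            "clone_id": clone_matrix.clone_ids,
            "size": sizes.astype(int),
            "n_cell_types": n_types.astype(int),
        }
    )
    df = df.sort_values(
        ["size", "clone_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df


def barcode_statistics(clone_matrix: CloneMatrix) -> pd.DataFrame:
    """Per-cell-type barcode diversity and barcoded-cell counts."""
    n_barcodes = (clone_matrix.counts > 0).sum(axis=0)
    n_cells = clone_matrix.counts.sum(axis=0)
    return pd.DataFrame(
        {
            "cell_type": clone_matrix.column_labels,
            "n_unique_barcodes": n_barcodes.astype(int),
            "n_barcoded_cells": n_cells.astype(int),
        }
    )
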