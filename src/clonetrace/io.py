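"""Domain types and readers/writers for the external formats the pipeline touches.

The central object is the :class:`CloneMatrix`, an integer clone x cell-type
(or clone x group) count table — the "barcode signature" substrate that fate
and lineage analysis operate on.  Everything else is plumbing around the
standard single-cell and genomics text formats: TSV metadata, MTX count
matrices, BED peaks, FASTA sequences and MEME/JASPAR motif files.

Coordinates follow BED semantics (0-based, half-open) throughout; peaks are
treated as unstranded.  Category order is first-appearance order in the input
and is preserved in all outputs so runs are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CellRecord",
    "BarcodeAssignment",
    "CloneMatrix",
    "CountMatrix",
    "PeakRegion",
    "Pwm",
    "CloneTraceFormatError",
    "read_clone_matrix",
    "write_clone_matrix",
    "build_clone_matrix",
    "read_cell_metadata",
    "write_cell_metadata",
    "read_barcode_assignments",
    "write_barcode_assignments",
    "read_count_matrix",
    "write_count_matrix",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_motifs",
    "write_motifs_meme",
    "write_table",
]


class CloneTraceFormatError(ValueError):
    """Malformed input file (bad record, wrong dtype, duplicate id...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellRecord:
    """One profiled cell: identity, state label and (optional) clone.

    ``clone_id`` is absent until barcode resolution assigns the cell to a
    clone; ``group`` carries orthogonal grouping information such as a time
    point.
    """

    cell_id: str
    cell_type: str
    sample: str = "sample1"
    group: str | None = None
    clone_id: str | None = None


@dataclass(frozen=True)
class BarcodeAssignment:
    """Raw barcode readout for one cell index, before resolution.

    A cell index may match several barcode sequences (sequencing error,
    ambient barcodes, true double labelling); each entry is a
    ``(barcode_id, count)`` pair with count >= 1.
    """

    cell_id: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"cell {self.cell_id!r}: empty barcode entry list")
        seen = set()
        for bc, count in self.entries:
            if count < 1:
                raise ValueError(
                    f"cell {self.cell_id!r}: barcode {bc!r} has count {count} < 1"
                )
            if bc in seen:
                raise ValueError(f"cell {self.cell_id!r}: duplicate barcode {bc!r}")
            seen.add(bc)


@dataclass
class CloneMatrix:
    """Integer clone x column (cell type or group) cell-count table."""

    clone_ids: list[str]
    column_labels: list[str]
    counts: np.ndarray  # (n_clones, n_columns) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.clone_ids), len(self.column_labels)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.clone_ids)} clones x {len(self.column_labels)} columns"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise CloneTraceFormatError("clone matrix entries must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise CloneTraceFormatError("clone matrix entries must be non-negative")
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise CloneTraceFormatError("duplicate clone ids")
        if len(set(self.column_labels)) != len(self.column_labels):
            raise CloneTraceFormatError("duplicate column labels")
        row_sums = self.counts.sum(axis=1)
        if (row_sums == 0).any():
            bad = [c for c, s in zip(self.clone_ids, row_sums) if s == 0]
            raise ValueError(f"all-zero clone rows not allowed: {bad[:5]}")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.clone_ids), columns=list(self.column_labels)
        )

    def select_clones(self, clone_ids: Sequence[str]) -> "CloneMatrix":
        index = {c: i for i, c in enumerate(self.clone_ids)}
        rows = [index[c] for c in clone_ids]
        return CloneMatrix(list(clone_ids), list(self.column_labels), self.counts[rows])


@dataclass
class CountMatrix:
    """Feature x cell count matrix (genes for RNA, peaks for ATAC)."""

    feature_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray | scipy.sparse.spmatrix
    modality: str = "rna"  # "rna" | "atac"

    def __post_init__(self) -> None:
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with id lists"
            )
        dense = self.dense()
        if not np.isfinite(dense).all():
            raise ValueError("count matrix contains non-finite values")
        if (dense < 0).any():
            raise ValueError("count matrix contains negative values")

    def dense(self) -> np.ndarray:
        if scipy.sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


@dataclass(frozen=True)
class PeakRegion:
    """Genomic interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    peak_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"peak {self.peak_id!r}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class Pwm:
    """Position probability matrix for a TF binding motif (rows A,C,G,T)."""

    motif_id: str
    matrix: np.ndarray  # (4, L) column-stochastic
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # (4,) base frequencies

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id!r}: matrix must be 4 x L, L >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id!r}: columns must sum to 1")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"motif {self.motif_id!r}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "Pwm":
        # A<->T, C<->G and reversed position order
        return Pwm(self.motif_id, self.matrix[::-1, ::-1].copy(), self.background[::-1].copy())


# ---------------------------------------------------------------------------
# clone matrix I/O
# ---------------------------------------------------------------------------


def read_clone_matrix(path: str | Path) -> CloneMatrix:
    """Read a clone x cell-type count table (TSV; comma also accepted).

    First column holds clone ids, header row the column labels.  All-zero
    clone rows carry no information and are dropped with a warning.
    """
    path = Path(path)
    sep = "\t"
    with open(path) as fh:
        header = fh.readline()
    if "\t" not in header and "," in header:
        sep = ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise CloneTraceFormatError(f"{path}: duplicate clone id(s): {dup[:5]}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number) or not np.all(
            vals == np.floor(vals)
        ):
            bad = vals.index[
                ~vals.apply(lambda v: isinstance(v, (int, np.integer)) or float(v).is_integer())
            ]
            row = bad[0] if len(bad) else "?"
            raise CloneTraceFormatError(
                f"{path}: non-integer cell at row {row!r}, column {col!r}"
            )
        if (vals < 0).any():
            row = vals.index[vals < 0][0]
            raise CloneTraceFormatError(
                f"{path}: negative cell at row {row!r}, column {col!r}"
            )
    counts = df.to_numpy(dtype=np.int64)
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        dropped = df.index[~keep].tolist()
        logger.warning(
            "%s: dropped %d all-zero clone row(s): %s",
            path,
            len(dropped),
            dropped[:5],
        )
    if not keep.any():
        raise CloneTraceFormatError(f"{path}: no clone with nonzero counts")
    return CloneMatrix(
        [str(c) for c in df.index[keep]],
        [str(c) for c in df.columns],
        counts[keep],
    )


def write_clone_matrix(matrix: CloneMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="clone_id")


def build_clone_matrix(cells: Iterable[CellRecord], by: str = "cell_type") -> CloneMatrix:
    """Tabulate clone-assigned cells into a CloneMatrix.

    ``by`` selects the column partition: "cell_type" (default) or "group".
    Entry (beta, A) counts the cells of clone beta carrying label A; the
    matrix total therefore equals the number of clone-assigned input cells.
    """
    if by not in ("cell_type", "group"):
        raise ValueError(f"by must be 'cell_type' or 'group', got {by!r}")
    clones: list[str] = []
    labels: list[str] = []
    clone_index: dict[str, int] = {}
    label_index: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    for cell in cells:
        if cell.clone_id is None:
            continue
        label = cell.cell_type if by == "cell_type" else cell.group
        if label is None:
            raise ValueError(f"cell {cell.cell_id!r} lacks a {by!r} label")
        if cell.clone_id not in clone_index:
            clone_index[cell.clone_id] = len(clones)
            clones.append(cell.clone_id)
        if label not in label_index:
            label_index[label] = len(labels)
            labels.append(label)
        pairs.append((clone_index[cell.clone_id], label_index[label]))
    if not pairs:
        raise ValueError("no clone-assigned cells to tabulate")
    counts = np.zeros((len(clones), len(labels)), dtype=np.int64)
    for i, j in pairs:
        counts[i, j] += 1
    return CloneMatrix(clones, labels, counts)


# ---------------------------------------------------------------------------
# cell metadata and barcode assignments
# ---------------------------------------------------------------------------


def read_cell_metadata(path: str | Path) -> list[CellRecord]:
    """Read per-cell metadata TSV (cell_id, cell_type, sample[, group, clone_id])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise CloneTraceFormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise CloneTraceFormatError(f"{path}: duplicate cell id(s): {dup[:5]}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _get(key: str) -> str | None:
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        records.append(
            CellRecord(
                cell_id=d["cell_id"],
                cell_type=d["cell_type"],
                sample=_get("sample") or "sample1",
                group=_get("group"),
                clone_id=_get("clone_id"),
            )
        )
    return records


def write_cell_metadata(cells: Sequence[CellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "cell_type": [c.cell_type for c in cells],
            "sample": [c.sample for c in cells],
            "group": [c.group if c.group is not None else "" for c in cells],
            "clone_id": [c.clone_id if c.clone_id is not None else "" for c in cells],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_barcode_assignments(path: str | Path) -> list[BarcodeAssignment]:
    """Read raw barcode-cell assignment TSV (cell_id, barcode_id, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "barcode_id": str})
    missing = {"cell_id", "barcode_id", "count"} - set(df.columns)
    if missing:
        raise CloneTraceFormatError(f"{path}: missing column(s) {sorted(missing)}")
    out: list[BarcodeAssignment] = []
    order: list[str] = []
    grouped: dict[str, list[tuple[str, int]]] = {}
    for row in df.itertuples(index=False):
        if row.cell_id not in grouped:
            grouped[row.cell_id] = []
            order.append(row.cell_id)
        grouped[row.cell_id].append((row.barcode_id, int(row.count)))
    for cid in order:
        out.append(BarcodeAssignment(cid, tuple(grouped[cid])))
    return out


def write_barcode_assignments(
    assignments: Sequence[BarcodeAssignment], path: str | Path
) -> None:
    rows = [
        (a.cell_id, bc, count) for a in assignments for bc, count in a.entries
    ]
    pd.DataFrame(rows, columns=["cell_id", "barcode_id", "count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# count matrices (MTX + row/column name files)
# ---------------------------------------------------------------------------


def read_count_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    cells_path: str | Path,
    modality: str = "rna",
) -> CountMatrix:
    """Read MatrixMarket counts plus one-name-per-line feature/cell files."""
    mat = scipy.io.mmread(str(mtx_path)).tocsr()
    features = Path(features_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    return CountMatrix(features, cells, mat, modality=modality)


def write_count_matrix(
    matrix: CountMatrix,
    mtx_path: str | Path,
    features_path: str | Path,
    cells_path: str | Path,
) -> None:
    values = matrix.values
    if not scipy.sparse.issparse(values):
        values = scipy.sparse.coo_matrix(values)
    scipy.io.mmwrite(str(mtx_path), values)
    Path(features_path).write_text("\n".join(matrix.feature_ids) + "\n")
    Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n")


# ---------------------------------------------------------------------------
# BED / FASTA
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[PeakRegion]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CloneTraceFormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CloneTraceFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            peak_id = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
            try:
                peaks.append(PeakRegion(fields[0], start, end, peak_id))
            except ValueError as exc:
                raise CloneTraceFormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Sequence[PeakRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# motifs (MEME minimal / JASPAR)
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def read_motifs(path: str | Path) -> list[Pwm]:
    """Read PWMs from a MEME (minimal) or JASPAR text file.

    JASPAR count matrices are normalized column-wise to probabilities; the
    MEME background line, when present, populates ``Pwm.background``.
    """
    from Bio import motifs as bio_motifs

    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("MEME version"):
        fmt = "minimal"
    elif stripped.startswith(">"):
        fmt = "jaspar"
    else:
        raise CloneTraceFormatError(f"{path}: unrecognized motif file format")
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, fmt)
        except Exception as exc:
            raise CloneTraceFormatError(f"{path}: motif parse failure: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _BASES], dtype=float)
        col_sums = counts.sum(axis=0)
        if (col_sums <= 0).any():
            raise CloneTraceFormatError(
                f"{path}: motif {m.name!r} has an empty matrix column"
            )
        matrix = counts / col_sums
        background = np.full(4, 0.25)
        if getattr(m, "background", None):
            bg = np.array([m.background.get(b, 0.0) for b in _BASES], dtype=float)
            if bg.sum() > 0:
                background = bg / bg.sum()
        motif_id = m.name or getattr(m, "base_id", None) or f"motif_{len(out) + 1}"
        out.append(Pwm(str(motif_id), matrix, background))
    return out


def write_motifs_meme(pwms: Sequence[Pwm], path: str | Path) -> None:
    """Write PWMs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write(
                "Background letter frequencies\n"
                + " ".join(f"{b} {p:.5f}" for b, p in zip(_BASES, bg))
                + "\n\n"
            )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 1000000 E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
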