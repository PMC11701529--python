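"""Synthetic lineage-tracing experiments with planted ground truth.

The generator emulates a LARRY-style experiment: barcoded progenitors
(clones) propagate into a panel of haematopoietic cell types.  Balanced
clones draw their cell types multinomially from the background proportions;
a configurable fraction of clones is fate-biased, placing ``bias_strength``
of its mass on one target type and spreading the remainder over the other
types proportionally to background.  Barcode detection is Bernoulli dropout
per cell; a fraction of detected cells additionally picks up a second
spurious barcode with a count no larger than the primary's.  A fraction of
barcodes is planted as multi-progenitor (initial-stage count 2), the
substrate for high-confidence filtering.

Gene expression is negative-binomial per gene with planted fold changes in
progenitor cells of clones biased toward two designated contrast targets,
providing ground truth for the differential module.  Peak sequences carry a
planted motif at different rates in foreground and background region sets.

Every stage draws from an independent substream spawned from the single
config seed, so outputs are bit-reproducible and stages can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    BarcodeAssignment,
    CellRecord,
    CloneMatrix,
    CountMatrix,
    PeakRegion,
    Pwm,
    build_clone_matrix,
    write_barcode_assignments,
    write_bed,
    write_cell_metadata,
    write_clone_matrix,
    write_count_matrix,
    write_fasta,
    write_motifs_meme,
    write_table,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticExperiment",
    "simulate_experiment",
    "benchmark_config",
    "null_config",
]

DEFAULT_CELL_TYPES: tuple[tuple[str, float], ...] = (
    ("HSPC", 0.40),
    ("Monocyte", 0.15),
    ("Neutrophil", 0.15),
    ("Erythroid", 0.10),
    ("Lymphoid", 0.10),
    ("Basophil", 0.05),
    ("Megakaryocyte", 0.05),
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror a LARRY-style in vitro haematopoiesis experiment at the
    ten-thousand-cell scale: ~2,000 clones over HSPC plus six mature types,
    log-normal clone sizes, 30% fate-biased clones placing 80% of their
    mass on one target, 80% barcode detection, 10% multi-progenitor
    barcodes and 5% multi-barcode noise cells.
    """

    seed: int
    n_clones: int = 2000
    clone_size_meanlog: float = 1.1
    clone_size_sdlog: float = 0.8
    cell_types: tuple[tuple[str, float], ...] = DEFAULT_CELL_TYPES
    frac_biased_clones: float = 0.3
    bias_strength: float = 0.8
    detection_rate: float = 0.8
    frac_multibarcode_cells: float = 0.05
    frac_multiprogenitor_barcodes: float = 0.1
    # expression panel
    n_genes: int = 200
    n_de_genes: int = 20
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.5
    base_expression_mean: float = 5.0
    # motif benchmark
    n_fg_regions: int = 50
    n_bg_regions: int = 50
    region_length: int = 200
    motif_fg_rate: float = 0.8
    motif_bg_rate: float = 0.1
    n_decoy_motifs: int = 4

    def __post_init__(self) -> None:
        fracs = {
            "frac_biased_clones": self.frac_biased_clones,
            "bias_strength": self.bias_strength,
            "detection_rate": self.detection_rate,
            "frac_multibarcode_cells": self.frac_multibarcode_cells,
            "frac_multiprogenitor_barcodes": self.frac_multiprogenitor_barcodes,
            "motif_fg_rate": self.motif_fg_rate,
            "motif_bg_rate": self.motif_bg_rate,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.bias_strength <= 0 or self.detection_rate <= 0:
            raise ValueError("bias_strength and detection_rate must be > 0")
        if len(self.cell_types) < 2 and self.frac_biased_clones > 0:
            raise ValueError("fate bias needs at least 2 cell types")
        props = np.array([p for _, p in self.cell_types], dtype=float)
        if (props <= 0).any():
            raise ValueError("background proportions must be positive")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")

    @property
    def type_names(self) -> list[str]:
        return [t for t, _ in self.cell_types]

    @property
    def background_props(self) -> np.ndarray:
        props = np.array([p for _, p in self.cell_types], dtype=float)
        return props / props.sum()


@dataclass
class SyntheticTruth:
    """Planted ground truth, the oracle every recovery test compares against."""

    clone_labels: dict[str, str]  # clone -> target type or "balanced"
    cell_clone: dict[str, str]  # every cell's true clone (incl. undetected)
    cell_detected: dict[str, bool]
    multiprogenitor_barcodes: list[str]
    de_genes: dict[str, float]  # gene -> planted log2fc (A vs B contrast)
    contrast_targets: tuple[str, str]  # the two bias targets carrying DE
    planted_motif_id: str
    region_planted: dict[str, bool]
    foreground_regions: list[str]
    background_regions: list[str]


@dataclass
class SyntheticExperiment:
    """In-memory synthetic experiment plus its truth ledger."""

    config: SimConfig
    cells: list[CellRecord]  # observed metadata (no clone ids)
    assignments: list[BarcodeAssignment]
    clone_matrix: CloneMatrix  # from true clones of detected cells
    initial_counts: dict[str, int]
    counts: CountMatrix | None
    peaks: list[PeakRegion]
    sequences: dict[str, str]
    motifs: list[Pwm]
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> None:
        """Emit every file a real experiment would provide, plus the truth."""
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cell_metadata(self.cells, out / "cells.tsv")
        write_barcode_assignments(self.assignments, out / "assignments.tsv")
        write_clone_matrix(self.clone_matrix, out / "clone_matrix.tsv")
        pd.DataFrame(
            sorted(self.initial_counts.items()), columns=["clone_id", "initial_cells"]
        ).to_csv(out / "initial_counts.tsv", sep="\t", index=False)
        if self.counts is not None:
            write_count_matrix(
                self.counts, out / "counts.mtx", out / "features.txt", out / "cells.txt"
            )
        if self.peaks:
            write_bed(self.peaks, out / "peaks.bed")
            write_fasta(self.sequences, out / "peaks.fasta")
        if self.motifs:
            write_motifs_meme(self.motifs, out / "motifs.meme")
        truth = self.truth
        write_table(
            pd.DataFrame(
                sorted(truth.clone_labels.items()), columns=["clone_id", "true_label"]
            ),
            out / "truth_clones.tsv",
        )
        write_table(
            pd.DataFrame(
                [
                    (cid, truth.cell_clone[cid], int(truth.cell_detected[cid]))
                    for cid in sorted(truth.cell_clone)
                ],
                columns=["cell_id", "true_clone", "detected"],
            ),
            out / "truth_cells.tsv",
        )
        write_table(
            pd.DataFrame(
                sorted(truth.de_genes.items()), columns=["gene", "planted_log2fc"]
            ),
            out / "truth_de_genes.tsv",
        )


def benchmark_config(seed: int, **overrides) -> SimConfig:
    """Fate-bias recovery benchmark: strongly biased clones of size >= 20.

    Clone sizes are drawn log-normal with median ~30 cells so that, after
    80% detection, planted biased clones typically keep >= 20 observed
    cells — the regime in which a fate-bias test is expected to have high
    power.  Expression and motif stages are not needed for this benchmark.
    """
    params = dict(
        seed=seed,
        n_clones=300,
        clone_size_meanlog=3.4,
        clone_size_sdlog=0.4,
        frac_biased_clones=0.3,
        bias_strength=0.8,
    )
    params.update(overrides)
    return SimConfig(**params)


def null_config(seed: int, **overrides) -> SimConfig:
    """Small no-bias experiment for type-I-error studies.

    Every clone draws its cell types from the shared background, so any
    fate-bias call is a false positive.
    """
    params = dict(
        seed=seed,
        n_clones=60,
        clone_size_meanlog=1.6,
        clone_size_sdlog=0.7,
        cell_types=(("HSPC", 0.4), ("Mono", 0.25), ("Neu", 0.2), ("Ery", 0.15)),
        frac_biased_clones=0.0,
    )
    params.update(overrides)
    return SimConfig(**params)


def _random_pwm(rng: np.random.Generator, length: int, motif_id: str) -> Pwm:
    matrix = rng.dirichlet(np.full(4, 0.5), size=length).T
    return Pwm(motif_id, matrix)


def _consensus_pwm(consensus: str, motif_id: str, dominant: float = 0.85) -> Pwm:
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    matrix = np.full((4, len(consensus)), (1 - dominant) / 3)
    for j, ch in enumerate(consensus):
        matrix[base_index[ch], j] = dominant
    return Pwm(motif_id, matrix)


def simulate_experiment(
    config: SimConfig,
    out_dir: str | Path | None = None,
    include_counts: bool = True,
    include_motifs: bool = True,
) -> SyntheticExperiment:
    """Generate a full synthetic scLT experiment under ``config``.

    Deterministic given ``config.seed``; optionally writes all files to
    ``out_dir``.  Expression and motif stages can be switched off for
    clone-level-only benchmarks.
    """
    root = np.random.default_rng(config.seed)
    rng_clone, rng_detect, rng_expr, rng_motif = root.spawn(4)

    type_names = config.type_names
    props = config.background_props
    n_types = len(type_names)

    # --- clones: sizes, labels, per-cell types ---
    sizes = np.maximum(
        1,
        np.round(
            rng_clone.lognormal(
                config.clone_size_meanlog, config.clone_size_sdlog, config.n_clones
            )
        ).astype(int),
    )
    clone_ids = [f"clone{idx:05d}" for idx in range(1, config.n_clones + 1)]
    n_biased = int(round(config.frac_biased_clones * config.n_clones))
    biased_idx = rng_clone.choice(config.n_clones, size=n_biased, replace=False)
    is_biased = np.zeros(config.n_clones, dtype=bool)
    is_biased[biased_idx] = True
    # biased clones target a non-progenitor type (never the first, most
    # abundant, type — bias toward the progenitor pool is modelled by the
    # background itself)
    target_pool = list(range(1, n_types)) if n_types > 1 else [0]
    targets = rng_clone.choice(target_pool, size=config.n_clones)

    clone_labels: dict[str, str] = {}
    cell_records: list[CellRecord] = []
    cell_true_clone: dict[str, str] = {}
    cell_counter = 0
    for i, clone in enumerate(clone_ids):
        if is_biased[i]:
            t = int(targets[i])
            p = np.zeros(n_types)
            others = np.delete(np.arange(n_types), t)
            p[t] = config.bias_strength
            rest = props[others] / props[others].sum()
            p[others] = (1 - config.bias_strength) * rest
            clone_labels[clone] = type_names[t]
        else:
            p = props
            clone_labels[clone] = "balanced"
        type_counts = rng_clone.multinomial(int(sizes[i]), p)
        for t_idx, k in enumerate(type_counts):
            for _ in range(int(k)):
                cell_counter += 1
                cid = f"cell{cell_counter:06d}"
                cell_records.append(
                    CellRecord(cid, type_names[t_idx], sample="S1", group="T1")
                )
                cell_true_clone[cid] = clone

    # --- detection dropout and multi-barcode noise ---
    n_cells = len(cell_records)
    detected = rng_detect.random(n_cells) < config.detection_rate
    primary_counts = 1 + rng_detect.poisson(4, size=n_cells)
    multibar = rng_detect.random(n_cells) < config.frac_multibarcode_cells
    assignments: list[BarcodeAssignment] = []
    cell_detected: dict[str, bool] = {}
    for k, cell in enumerate(cell_records):
        cell_detected[cell.cell_id] = bool(detected[k])
        if not detected[k]:
            continue
        clone = cell_true_clone[cell.cell_id]
        entries = [(clone, int(primary_counts[k]))]
        if multibar[k] and config.n_clones > 1:
            other = clone_ids[int(rng_detect.integers(config.n_clones))]
            if other != clone:
                noise_count = int(rng_detect.integers(1, primary_counts[k] + 1))
                entries.append((other, noise_count))
        assignments.append(BarcodeAssignment(cell.cell_id, tuple(entries)))

    # --- multi-progenitor barcodes (initial-stage counts) ---
    n_multi = int(round(config.frac_multiprogenitor_barcodes * config.n_clones))
    multi_idx = rng_detect.choice(config.n_clones, size=n_multi, replace=False)
    initial_counts = {c: 1 for c in clone_ids}
    multi_barcodes = sorted(clone_ids[int(i)] for i in multi_idx)
    for c in multi_barcodes:
        initial_counts[c] = 2

    # clone matrix over detected cells, true clone identity
    observed = [
        CellRecord(
            c.cell_id, c.cell_type, c.sample, c.group,
            clone_id=cell_true_clone[c.cell_id],
        )
        for k, c in enumerate(cell_records)
        if detected[k]
    ]
    clone_matrix = build_clone_matrix(observed, by="cell_type")
    initial_counts = {c: initial_counts[c] for c in clone_matrix.clone_ids}

    # --- expression with planted DE between two bias-target groups ---
    counts_matrix: CountMatrix | None = None
    de_genes: dict[str, float] = {}
    contrast = (type_names[1], type_names[2]) if n_types >= 3 else (
        type_names[-1], type_names[-1]
    )
    if include_counts:
        gene_ids = [f"gene{idx:04d}" for idx in range(1, config.n_genes + 1)]
        base_means = rng_expr.lognormal(
            np.log(config.base_expression_mean), 0.5, config.n_genes
        )
        de_pick = rng_expr.choice(config.n_genes, size=config.n_de_genes, replace=False)
        effect = np.zeros(config.n_genes)
        half = config.n_de_genes // 2
        effect[de_pick[:half]] = config.de_log2fc  # up in contrast[0]-biased cells
        effect[de_pick[half:]] = -config.de_log2fc  # up in contrast[1]-biased cells
        for g_idx in de_pick:
            de_genes[gene_ids[int(g_idx)]] = float(effect[int(g_idx)])
        lib = rng_expr.uniform(0.7, 1.3, n_cells)
        progenitor = type_names[0]
        mean_mat = np.empty((config.n_genes, n_cells))
        for k, cell in enumerate(cell_records):
            label = clone_labels[cell_true_clone[cell.cell_id]]
            shift = np.zeros(config.n_genes)
            if cell.cell_type == progenitor and label == contrast[0]:
                shift = np.where(effect > 0, effect, 0.0)
            elif cell.cell_type == progenitor and label == contrast[1]:
                shift = np.where(effect < 0, -effect, 0.0)
            mean_mat[:, k] = base_means * (2.0 ** shift) * lib[k]
        # NB2 sampling: Gamma-Poisson mixture with shape 1/dispersion
        r = 1.0 / config.nb_dispersion
        lam = rng_expr.gamma(r, mean_mat / r)
        values = rng_expr.poisson(lam).astype(np.int64)
        counts_matrix = CountMatrix(
            gene_ids, [c.cell_id for c in cell_records], values, modality="rna"
        )

    # --- peaks, sequences and motifs ---
    peaks: list[PeakRegion] = []
    sequences: dict[str, str] = {}
    motifs: list[Pwm] = []
    region_planted: dict[str, bool] = {}
    fg_ids: list[str] = []
    bg_ids: list[str] = []
    planted_id = "PLANTED_TGACTCAG"
    if include_motifs:
        consensus = "TGACTCAG"
        motifs = [_consensus_pwm(consensus, planted_id)]
        for m in range(config.n_decoy_motifs):
            motifs.append(_random_pwm(rng_motif, 8, f"DECOY{m + 1}"))
        n_regions = config.n_fg_regions + config.n_bg_regions
        for ridx in range(n_regions):
            in_fg = ridx < config.n_fg_regions
            rid = f"peak{ridx + 1:04d}"
            (fg_ids if in_fg else bg_ids).append(rid)
            seq = "".join(
                _BASES[rng_motif.integers(0, 4, config.region_length)]
            )
            rate = config.motif_fg_rate if in_fg else config.motif_bg_rate
            planted = bool(rng_motif.random() < rate)
            if planted:
                pos = int(
                    rng_motif.integers(0, config.region_length - len(consensus) + 1)
                )
                seq = seq[:pos] + consensus + seq[pos + len(consensus):]
            region_planted[rid] = planted
            sequences[rid] = seq
            start = 1000 * ridx
            peaks.append(PeakRegion("chr1", start, start + config.region_length, rid))

    truth = SyntheticTruth(
        clone_labels=clone_labels,
        cell_clone=cell_true_clone,
        cell_detected=cell_detected,
        multiprogenitor_barcodes=[
            c for c in multi_barcodes if c in set(clone_matrix.clone_ids)
        ],
        de_genes=de_genes,
        contrast_targets=contrast,
        planted_motif_id=planted_id,
        region_planted=region_planted,
        foreground_regions=fg_ids,
        background_regions=bg_ids,
    )
    experiment = SyntheticExperiment(
        config=config,
        cells=cell_records,
        assignments=assignments,
        clone_matrix=clone_matrix,
        initial_counts=initial_counts,
        counts=counts_matrix,
        peaks=peaks,
        sequences=sequences,
        motifs=motifs,
        truth=truth,
    )
    if out_dir is not None:
        experiment.write(out_dir)
    return experiment
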