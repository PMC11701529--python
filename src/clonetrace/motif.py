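"""PWM scanning with exact score-distribution thresholds, and enrichment.

A motif match is called when any window of a region, on either strand,
scores at least the log-odds threshold whose background tail probability
falls below ``p_cutoff`` (default 5e-5).  The null score distribution under
an i.i.d. 0-order background is computed exactly by dynamic programming over
motif positions on a discretized score grid, so the threshold is the
smallest score s with P(score >= s) <= p_cutoff — the same contract as
binary matchMotifs-style scanners.

Enrichment between a foreground and a background region set is a one-sided
hypergeometric test on match counts (the same Fisher routine used for clone
fate bias), BH-adjusted across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .fate import bh_adjust, fisher_exact_one_sided
from .io import Pwm

__all__ = [
    "MotifMatchMatrix",
    "MotifEnrichment",
    "pwm_score_threshold",
    "scan_regions",
    "motif_enrichment",
]

#: score discretization grain in log2-odds units
SCORE_GRAIN = 1e-3
#: pseudo-probability added to PWM entries before log-odds
PWM_PSEUDOCOUNT = 0.008

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


@dataclass
class MotifMatchMatrix:
    """Boolean region x motif match table."""

    region_ids: list[str]
    motif_ids: list[str]
    matches: np.ndarray

    def __post_init__(self) -> None:
        self.matches = np.asarray(self.matches, dtype=bool)
        if self.matches.shape != (len(self.region_ids), len(self.motif_ids)):
            raise ValueError("matches shape inconsistent with id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matches, index=list(self.region_ids), columns=list(self.motif_ids)
        )


@dataclass(frozen=True)
class MotifEnrichment:
    """Foreground-vs-background enrichment result for one motif."""

    motif_id: str
    n_fg_match: int
    n_fg: int
    n_bg_match: int
    n_bg: int
    p_value: float
    fdr: float
    log2_enrichment: float


def _int_scores(pwm: Pwm, background: np.ndarray) -> np.ndarray:
    """Integer-discretized log2-odds score table, shape (4, L)."""
    if (background <= 0).any():
        raise ValueError(f"motif {pwm.motif_id!r}: background has a zero frequency")
    probs = pwm.matrix + PWM_PSEUDOCOUNT
    probs = probs / probs.sum(axis=0)
    if (probs <= 0).any():
        raise ValueError(f"motif {pwm.motif_id!r}: degenerate column after pseudocount")
    logodds = np.log2(probs / background[:, None])
    return np.round(logodds / SCORE_GRAIN).astype(np.int64)


def _score_distribution(
    scores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of total integer score under the background.

    Dynamic programming over positions: the distribution after k positions
    is the convolution of the per-position 4-point distributions.  Returns
    (support offsets array start..stop, probabilities).
    """
    lo = int(scores.min(axis=0).sum())
    hi = int(scores.max(axis=0).sum())
    dist = np.zeros(hi - lo + 1)
    # running support window [cur_lo, cur_hi]
    cur_lo = 0
    dist0 = np.array([1.0])
    for j in range(scores.shape[1]):
        col = scores[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(dist0) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(col[b]) - new_lo
            new[off : off + len(dist0)] += background[b] * dist0
        dist0 = new
        cur_lo = new_lo
    dist[cur_lo - lo : cur_lo - lo + len(dist0)] = dist0
    support = np.arange(lo, hi + 1)
    return support, dist


def pwm_score_threshold(
    pwm: Pwm,
    p_cutoff: float = 5e-5,
    background: Sequence[float] | None = None,
) -> int:
    """Smallest integer-grid score whose background tail is <= p_cutoff.

    If even the maximal achievable score has tail probability above
    ``p_cutoff`` the returned threshold is unattainable (max score + 1) and
    the motif can never match — short motifs cannot reach stringent cutoffs.
    """
    if not 0 < p_cutoff < 1:
        raise ValueError("p_cutoff must be in (0, 1)")
    bg = pwm.background if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    scores = _int_scores(pwm, bg)
    support, probs = _score_distribution(scores, bg)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= support[i])
    ok = np.nonzero(tail <= p_cutoff + 1e-15)[0]
    if ok.size == 0:
        return int(support[-1]) + 1
    return int(support[ok[0]])


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[ch] for ch in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGTN character in sequence: {exc}") from exc


def _scan_one(
    codes: np.ndarray, scores: np.ndarray, threshold: int
) -> bool:
    length = scores.shape[1]
    if codes.size < length:
        return False
    windows = sliding_window_view(codes, length)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return False
    w = windows[valid]
    total = scores[w, np.arange(length)].sum(axis=1)
    return bool((total >= threshold).any())


def scan_regions(
    pwms: Sequence[Pwm],
    sequences: Mapping[str, str],
    p_cutoff: float = 5e-5,
    background: Sequence[float] | None = None,
) -> MotifMatchMatrix:
    """Match each region sequence against each PWM on both strands.

    A region matches a motif iff any window on the forward or reverse
    strand reaches the motif's threshold; windows containing N never match.
    The reverse strand is scanned with the reverse-complemented PWM (with
    its own threshold, since an asymmetric background is not strand-
    symmetric).
    """
    region_ids = list(sequences)
    encoded = {rid: _encode(sequences[rid]) for rid in region_ids}
    matches = np.zeros((len(region_ids), len(pwms)), dtype=bool)
    for j, pwm in enumerate(pwms):
        bg = pwm.background if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        rc = pwm.reverse_complement()
        variants = []
        for variant in (pwm, Pwm(pwm.motif_id, rc.matrix, bg)):
            scores = _int_scores(variant, bg)
            thr = pwm_score_threshold(variant, p_cutoff, bg)
            variants.append((scores, thr))
        for i, rid in enumerate(region_ids):
            codes = encoded[rid]
            matches[i, j] = any(
                _scan_one(codes, scores, thr) for scores, thr in variants
            )
    return MotifMatchMatrix(region_ids, [p.motif_id for p in pwms], matches)


def estimate_background(sequences: Mapping[str, str]) -> np.ndarray:
    """0-order background base frequencies from a sequence set (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences.values():
        codes = _encode(seq)
        for b in range(4):
            counts[b] += int((codes == b).sum())
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def motif_enrichment(
    matches: MotifMatchMatrix,
    foreground: Sequence[str],
    background: Sequence[str],
) -> list[MotifEnrichment]:
    """Per-motif hypergeometric enrichment of matches in foreground regions.

    log2_enrichment compares match rates with 0.5 pseudocounts; results are
    sorted by FDR, then p, then motif id, and are invariant to region order.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg or not bg:
        raise ValueError("foreground and background must both be non-empty")
    overlap = fg & bg
    if overlap:
        raise ValueError(f"foreground/background overlap: {sorted(overlap)[:5]}")
    index = {rid: i for i, rid in enumerate(matches.region_ids)}
    missing = (fg | bg) - set(index)
    if missing:
        raise ValueError(f"unknown region id(s): {sorted(missing)[:5]}")
    fg_rows = [index[r] for r in sorted(fg)]
    bg_rows = [index[r] for r in sorted(bg)]
    n_fg, n_bg = len(fg_rows), len(bg_rows)
    records = []
    for j, motif_id in enumerate(matches.motif_ids):
        a = int(matches.matches[fg_rows, j].sum())
        c = int(matches.matches[bg_rows, j].sum())
        _, p = fisher_exact_one_sided(a, n_fg - a, c, n_bg - c)
        lfc = float(
            np.log2(((a + 0.5) * (n_bg + 0.5)) / ((c + 0.5) * (n_fg + 0.5)))
        )
        records.append((motif_id, a, n_fg, c, n_bg, p, lfc))
    fdrs = bh_adjust([r[5] for r in records])
    out = [
        MotifEnrichment(m, a, nf, c, nb, p, float(q), lfc)
        for (m, a, nf, c, nb, p, lfc), q in zip(records, fdrs)
    ]
    out.sort(key=lambda e: (e.fdr, e.p_value, e.motif_id))
    return out


def enrichment_to_frame(results: Sequence[MotifEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "n_fg_match": [r.n_fg_match for r in results],
            "n_fg": [r.n_fg for r in results],
            "n_bg_match": [r.n_bg_match for r in results],
            "n_bg": [r.n_bg for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "log2_enrichment": [r.log2_enrichment for r in results],
        }
    )
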