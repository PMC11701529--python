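"""Clone fate analysis: fate-outcome normalization and fate-bias testing.

The fate map normalizes each clone's barcode counts to a distribution over
cell types:

    value(beta, A) = counts of barcode beta in cell type A
                     / counts of barcode beta in all cell types

Fate bias asks whether a clone's occupancy of a target cell-type set exceeds
what random sampling of all barcoded cells would give.  Each (clone, target)
pair yields a 2x2 table

    a = clone cells in target          b = clone cells elsewhere
    c = other-clone cells in target    d = other-clone cells elsewhere

tested with a one-sided (enrichment) Fisher exact test; p-values are
Benjamini-Hochberg adjusted jointly over all clone x target tests, and a
clone is called biased toward the target of its minimum-FDR significant
enriched test (FDR < alpha and odds ratio > 1), otherwise "balanced".

The Fisher p-value is computed with exact integer arithmetic (sums of
binomial coefficients), so it agrees with hypergeometric enumeration to
floating-point rounding only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CloneMatrix

__all__ = [
    "FateMap",
    "FateBiasCall",
    "BALANCED",
    "UNTESTED",
    "fate_mapping",
    "fisher_exact_one_sided",
    "bh_adjust",
    "clone_fate_bias",
    "fate_bias_test_table",
    "summarize_fate_bias",
]

BALANCED = "balanced"
UNTESTED = "untested"


@dataclass
class FateMap:
    """Row-stochastic clone x cell-type fate-outcome matrix."""

    clone_ids: list[str]
    column_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.clone_ids), len(self.column_labels)):
            raise ValueError("values shape inconsistent with id lists")
        if (self.values < 0).any():
            raise ValueError("fate map values must be non-negative")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fate map rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.clone_ids), columns=list(self.column_labels)
        )


@dataclass(frozen=True)
class FateBiasCall:
    """Fate-bias verdict for one clone (winning target's 2x2 table)."""

    clone_id: str
    target_label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    fdr: float
    label: str

    @property
    def clone_size(self) -> int:
        return self.a + self.b


def fate_mapping(clone_matrix: CloneMatrix) -> FateMap:
    """Normalize each clone row to its distribution over cell types."""
    row_sums = clone_matrix.counts.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("clone matrix contains an all-zero row")
    values = clone_matrix.counts / row_sums[:, None]
    return FateMap(
        list(clone_matrix.clone_ids), list(clone_matrix.column_labels), values
    )


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    ad, bc = a * d, b * c
    if bc > 0:
        return ad / bc
    return math.inf if ad > 0 else math.nan


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Enrichment-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p)`` with p = P(X >= a) for
    X ~ Hypergeometric(N = a+b+c+d, K = a+c, n = a+b), evaluated with exact
    integer arithmetic.  The odds ratio is ad/bc, infinity when bc = 0 with
    ad > 0.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("all-zero 2x2 table")
    if a + b == 0:
        raise ValueError("empty first row (a + b = 0)")
    big_k = a + c  # successes in population
    n = a + b  # draws
    k_max = min(n, big_k)
    numerator = sum(
        math.comb(big_k, k) * math.comb(n_total - big_k, n - k)
        for k in range(a, k_max + 1)
    )
    p = numerator / math.comb(n_total, n)
    return _odds_ratio(a, b, c, d), min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _default_targets(labels: Sequence[str]) -> list[tuple[str, frozenset[str]]]:
    return [(label, frozenset([label])) for label in labels]


def _normalize_targets(
    clone_matrix: CloneMatrix,
    targets: Sequence[tuple[str, Sequence[str]]] | Mapping[str, Sequence[str]] | None,
) -> list[tuple[str, frozenset[str]]]:
    if targets is None:
        return _default_targets(clone_matrix.column_labels)
    if isinstance(targets, Mapping):
        targets = list(targets.items())
    known = set(clone_matrix.column_labels)
    out = []
    for name, labels in targets:
        labels = frozenset([labels] if isinstance(labels, str) else labels)
        unknown = labels - known
        if unknown:
            raise ValueError(
                f"target {name!r} references unknown label(s): {sorted(unknown)}"
            )
        out.append((str(name), labels))
    return out


def _all_tests(
    clone_matrix: CloneMatrix,
    targets: list[tuple[str, frozenset[str]]],
    min_clone_size: int,
) -> pd.DataFrame:
    counts = clone_matrix.counts
    sizes = counts.sum(axis=1)
    grand_total = int(counts.sum())
    col_index = {lab: j for j, lab in enumerate(clone_matrix.column_labels)}
    rows = []
    for i, clone in enumerate(clone_matrix.clone_ids):
        size = int(sizes[i])
        if size < min_clone_size:
            continue
        for name, labels in targets:
            cols = [col_index[lab] for lab in labels]
            a = int(counts[i, cols].sum())
            b = size - a
            target_total = int(counts[:, cols].sum())
            c = target_total - a
            d = grand_total - size - c
            odds, p = fisher_exact_one_sided(a, b, c, d)
            rows.append((clone, name, a, b, c, d, odds, p))
    return pd.DataFrame(
        rows,
        columns=["clone_id", "target", "a", "b", "c", "d", "odds_ratio", "p_value"],
    )


def fate_bias_test_table(
    clone_matrix: CloneMatrix,
    targets: Sequence[tuple[str, Sequence[str]]] | Mapping[str, Sequence[str]] | None = None,
    min_clone_size: int = 2,
    bh_scope: str = "global",
) -> pd.DataFrame:
    """All (clone x target) enrichment tests with BH-adjusted FDR column.

    ``bh_scope`` = "global" pools every test into one BH family (default);
    "per_target" adjusts within each target separately.
    """
    norm_targets = _normalize_targets(clone_matrix, targets)
    tests = _all_tests(clone_matrix, norm_targets, min_clone_size)
    if tests.empty:
        return tests.assign(fdr=pd.Series(dtype=float))
    if bh_scope == "global":
        tests["fdr"] = bh_adjust(tests["p_value"].to_numpy())
    elif bh_scope == "per_target":
        tests["fdr"] = np.nan
        for _, idx in tests.groupby("target").groups.items():
            tests.loc[idx, "fdr"] = bh_adjust(tests.loc[idx, "p_value"].to_numpy())
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    return tests


def clone_fate_bias(
    clone_matrix: CloneMatrix,
    targets: Sequence[tuple[str, Sequence[str]]] | Mapping[str, Sequence[str]] | None = None,
    alpha: float = 0.05,
    min_clone_size: int = 2,
    bh_scope: str = "global",
) -> list[FateBiasCall]:
    """Call fate bias per clone.

    Targets default to one singleton set per cell type; named groupings
    (e.g. ``{"lymphoid": ["T", "B", "NK"]}``) may be supplied.  A clone is
    labelled "<target> biased" by its minimum-FDR significant enriched test
    (FDR < alpha, odds ratio > 1); ties on FDR break by larger in-target
    count ``a``, then lexicographic target name.  Clones smaller than
    ``min_clone_size`` are reported as "untested" — a single cell cannot
    evidence bias.
    """
    tests = fate_bias_test_table(clone_matrix, targets, min_clone_size, bh_scope)
    calls: list[FateBiasCall] = []
    by_clone = (
        {k: g for k, g in tests.groupby("clone_id", sort=False)}
        if not tests.empty
        else {}
    )
    sizes = clone_matrix.counts.sum(axis=1)
    grand_total = clone_matrix.total
    for i, clone in enumerate(clone_matrix.clone_ids):
        size = int(sizes[i])
        if size < min_clone_size:
            calls.append(
                FateBiasCall(
                    clone, "", size, 0, grand_total - size, 0,
                    math.nan, math.nan, math.nan, UNTESTED,
                )
            )
            continue
        g = by_clone[clone]
        sig = g[(g["fdr"] < alpha) & (g["odds_ratio"] > 1)]
        if len(sig):
            win = sig.sort_values(
                ["fdr", "a", "target"], ascending=[True, False, True], kind="stable"
            ).iloc[0]
            label = f"{win['target']} biased"
        else:
            # report the best (smallest-FDR) test for context
            win = g.sort_values(
                ["fdr", "a", "target"], ascending=[True, False, True], kind="stable"
            ).iloc[0]
            label = BALANCED
        calls.append(
            FateBiasCall(
                clone,
                str(win["target"]),
                int(win["a"]),
                int(win["b"]),
                int(win["c"]),
                int(win["d"]),
                float(win["odds_ratio"]),
                float(win["p_value"]),
                float(win["fdr"]),
                label,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[FateBiasCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in calls],
            "target": [c.target_label for c in calls],
            "a": [c.a for c in calls],
            "b": [c.b for c in calls],
            "c": [c.c for c in calls],
            "d": [c.d for c in calls],
            "odds_ratio": [c.odds_ratio for c in calls],
            "p_value": [c.p_value for c in calls],
            "fdr": [c.fdr for c in calls],
            "label": [c.label for c in calls],
        }
    )


def summarize_fate_bias(
    calls: Sequence[FateBiasCall],
    restrict_to: Sequence[str] | None = None,
    weight: str = "clone",
) -> pd.DataFrame:
    """Fraction of clones (or cells) per fate-bias label.

    ``weight`` = "clone" counts clones; "cell" weights each clone by its
    size, answering what fraction of barcoded cells sits in clones of each
    bias.  Both weightings are reported by the CLI since field usage varies.
    """
    if not calls:
        raise ValueError("empty call list")
    if restrict_to is not None:
        keep = set(restrict_to)
        calls = [c for c in calls if c.clone_id in keep]
        if not calls:
            raise ValueError("restriction removed every call")
    if weight == "clone":
        weights = {c.clone_id: 1 for c in calls}
    elif weight == "cell":
        weights = {c.clone_id: c.clone_size for c in calls}
    else:
        raise ValueError(f"unknown weight {weight!r}")
    totals: dict[str, float] = {}
    n_clones: dict[str, int] = {}
    for c in calls:
        totals[c.label] = totals.get(c.label, 0) + weights[c.clone_id]
        n_clones[c.label] = n_clones.get(c.label, 0) + 1
    grand = sum(totals.values())
    labels = sorted(totals)
    return pd.DataFrame(
        {
            "label": labels,
            "n_clones": [n_clones[k] for k in labels],
            "fraction": [totals[k] / grand for k in labels],
        }
    )
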