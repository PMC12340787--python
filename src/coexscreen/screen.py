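"""Bulk and metacell screening statistics.

A reference-gene correlation screen asks: across a compendium of samples (or
metacells), which candidate genes track a reference gene's expression?  For
the collagen IV screen the reference is *Col4a1*, the candidates are the
prolyl-4-hydroxylase-alpha-related genes, and the readout is the Pearson
correlation r of each candidate with the reference, ranked descending.

This module also provides the display normalisation (per-gene division by the
row maximum), ordinary-least-squares regression summaries for metacell
scatter plots, peak-time ordering for developmental time courses, and the
threshold-quadrant classification of metacells (e.g. "high Col4a1 (> 1) and
low candidate (< 0.1)").

Correlations are computed on raw expression values, never on max-normalized
ones: Pearson r is invariant to positive per-gene rescaling, and the
normalisation exists only for display.  An r that is undefined because either
vector has zero variance is reported as missing, never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionTable, MetacellMatrix
from .errors import DomainError, GeneLookupError, SpecificationError

__all__ = [
    "max_normalize",
    "pearson_r",
    "round_half_up",
    "CorrelationScreen",
    "CorrelationScreenResults",
    "correlation_screen",
    "groupwise_correlation",
    "fit_regression_line",
    "sort_by_peak_time",
    "quadrant_classify",
    "QuadrantCounts",
    "select_metacells",
    "max_over_genes",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed 2-dp conventions."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def max_normalize(table: ExpressionTable) -> ExpressionTable:
    """Divide each gene row by its maximum; all-zero rows stay all-zero.

    Output values lie in [0, 1]; this is the per-gene display scaling used
    for brightness-coded expression panels.
    """
    if np.any(table.values < 0):
        raise DomainError("max_normalize requires nonnegative values")
    row_max = table.values.max(axis=1)
    scale = np.where(row_max > 0, row_max, 1.0)
    return ExpressionTable(
        gene_symbols=list(table.gene_symbols),
        sample_labels=list(table.sample_labels),
        values=table.values / scale[:, None],
        dataset_id=table.dataset_id,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (undefined) when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class CorrelationScreenResults:
    """Ranked reference-gene correlations for a set of candidate genes.

    ``records`` has columns ``gene``, ``r``, ``n``, ``rank`` sorted by r
    descending (ties broken by candidate input order); candidates whose r is
    undefined (zero variance) are listed in ``undefined`` and excluded from
    the ranking.
    """

    reference_gene: str
    dataset_id: str
    records: pd.DataFrame
    undefined: list[str]

    def rank_of(self, gene: str) -> int:
        row = self.records[self.records["gene"] == gene]
        if row.empty:
            raise GeneLookupError(f"gene {gene!r} not in the ranking")
        return int(row["rank"].iloc[0])

    def r_of(self, gene: str) -> float:
        row = self.records[self.records["gene"] == gene]
        if row.empty:
            return float("nan")
        return float(row["r"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Reference-gene correlation screen",
            f"  reference: {self.reference_gene}   dataset: {self.dataset_id}",
            f"  candidates ranked: {len(self.records)}"
            + (f"   undefined r: {len(self.undefined)}" if self.undefined else ""),
            "",
            self.records.to_string(index=False),
        ]
        if self.undefined:
            lines.append("")
            lines.append("undefined (zero variance): " + ", ".join(self.undefined))
        return "\n".join(lines)


class CorrelationScreen:
    """Model object for the reference-gene correlation screen.

    Parameters
    ----------
    table:
        Expression table holding the reference and candidate genes.
    reference:
        Reference gene symbol (e.g. a collagen IV subunit).
    candidates:
        Candidate gene symbols to rank; order breaks ties.
    """

    def __init__(
        self, table: ExpressionTable, reference: str, candidates: list[str]
    ) -> None:
        if table.n_samples < 3:
            raise SpecificationError("correlation screen needs >= 3 samples")
        if reference not in table:
            raise GeneLookupError(f"reference gene {reference!r} not in table")
        for gene in candidates:
            if gene not in table:
                raise GeneLookupError(f"candidate gene {gene!r} not in table")
        self.table = table
        self.reference = reference
        self.candidates = list(candidates)

    def fit(self) -> CorrelationScreenResults:
        ref = self.table.row(self.reference)
        rows = []
        undefined = []
        for order, gene in enumerate(self.candidates):
            r = pearson_r(ref, self.table.row(gene))
            if math.isnan(r):
                undefined.append(gene)
            else:
                rows.append((gene, r, self.table.n_samples, order))
        frame = pd.DataFrame(rows, columns=["gene", "r", "n", "_order"])
        frame = frame.sort_values(
            ["r", "_order"], ascending=[False, True], kind="stable"
        ).drop(columns="_order")
        frame["rank"] = np.arange(1, len(frame) + 1)
        return CorrelationScreenResults(
            reference_gene=self.reference,
            dataset_id=self.table.dataset_id,
            records=frame.reset_index(drop=True),
            undefined=undefined,
        )


def correlation_screen(
    table: ExpressionTable, reference: str, candidates: list[str]
) -> CorrelationScreenResults:
    """Functional wrapper: rank candidates by Pearson r with the reference."""
    return CorrelationScreen(table, reference, candidates).fit()


def groupwise_correlation(
    matrix: MetacellMatrix,
    gene_a: str,
    gene_b: str,
    by_group: bool = False,
    min_group_size: int = 3,
) -> tuple[float, dict[str, float]]:
    """Pooled Pearson r of two genes over metacells, optionally per group.

    Groups with fewer than ``min_group_size`` metacells get an undefined
    (NaN) r.  Returns ``(pooled_r, {group: r})``; the per-group mapping is
    empty when ``by_group`` is false.
    """
    a = matrix.gene(gene_a)
    b = matrix.gene(gene_b)
    pooled = pearson_r(a, b)
    per_group: dict[str, float] = {}
    if by_group:
        for group in matrix.groups():
            mask = (matrix.group_labels == group).to_numpy()
            if mask.sum() < min_group_size:
                per_group[group] = float("nan")
            else:
                per_group[group] = pearson_r(a[mask], b[mask])
    return pooled, per_group


def fit_regression_line(
    matrix: MetacellMatrix, gene_x: str, gene_y: str
) -> tuple[float, float]:
    """Ordinary least squares of gene_y on gene_x over all metacells."""
    x = matrix.gene(gene_x)
    y = matrix.gene(gene_y)
    if np.ptp(x) == 0:
        raise DomainError(f"gene {gene_x!r} is constant; regression undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def sort_by_peak_time(table: ExpressionTable) -> list[str]:
    """Order genes by the sample index of their first-attained maximum.

    Earlier peaks come first; ties keep gene input order; all-zero genes are
    placed last (they have no peak).
    """
    if table.n_samples < 1:
        raise SpecificationError("need at least one sample")
    peaked = []
    flat = []
    for i, gene in enumerate(table.gene_symbols):
        row = table.values[i]
        if np.all(row == 0):
            flat.append(gene)
        else:
            peaked.append((int(np.argmax(row)), i, gene))
    peaked.sort(key=lambda t: (t[0], t[1]))
    return [g for _, _, g in peaked] + flat


@dataclass
class QuadrantCounts:
    """Metacell counts in the four strict-inequality threshold quadrants.

    ``hi`` is the "high expression" cutoff (strictly above) for both axes;
    ``lo`` is the "low expression" cutoff (strictly below) for the axis being
    called low.  Boundary values fall in no quadrant.  ``per_annotation``
    breaks each quadrant's count down by metacell group label.
    """

    gene_x: str
    gene_y: str
    hi_threshold: float
    lo_threshold: float
    counts: dict[str, int]
    per_annotation: dict[str, dict[str, int]]
    n_metacells: int

    QUADRANTS = ("x_hi_y_lo", "x_lo_y_hi", "x_hi_y_hi", "x_lo_y_lo")

    def summary(self) -> str:
        lines = [
            f"Quadrant classification: x={self.gene_x}, y={self.gene_y} "
            f"(hi > {self.hi_threshold:g}, lo < {self.lo_threshold:g})",
            f"  metacells: {self.n_metacells}",
        ]
        for q in self.QUADRANTS:
            breakdown = ", ".join(
                f"{k}: {v}" for k, v in sorted(self.per_annotation[q].items())
            )
            lines.append(f"  {q}: {self.counts[q]}" + (f"  [{breakdown}]" if breakdown else ""))
        return "\n".join(lines)


def quadrant_classify(
    matrix: MetacellMatrix, gene_x: str, gene_y: str, hi: float, lo: float
) -> QuadrantCounts:
    """Count metacells in the four high/low quadrants with strict inequalities.

    The quadrants are ``x_hi_y_lo`` (x > hi and y < lo), ``x_lo_y_hi``
    (x < hi and y > hi), ``x_hi_y_hi`` (both > hi) and ``x_lo_y_lo`` (x < hi
    and y < lo).  "High" is always a strict comparison with ``hi``; "low"
    with ``lo`` — exactly as thresholds like "> 1" and "< 0.1" are printed.
    """
    if lo > hi:
        raise SpecificationError("lo threshold must not exceed hi threshold")
    x = matrix.gene(gene_x)
    y = matrix.gene(gene_y)
    groups = matrix.group_labels.to_numpy()
    masks = {
        "x_hi_y_lo": (x > hi) & (y < lo),
        "x_lo_y_hi": (x < hi) & (y > hi),
        "x_hi_y_hi": (x > hi) & (y > hi),
        "x_lo_y_lo": (x < hi) & (y < lo),
    }
    counts = {q: int(m.sum()) for q, m in masks.items()}
    per_annotation = {
        q: {
            str(label): int(((groups == label) & m).sum())
            for label in pd.unique(groups[m])
        }
        for q, m in masks.items()
    }
    return QuadrantCounts(
        gene_x=gene_x,
        gene_y=gene_y,
        hi_threshold=hi,
        lo_threshold=lo,
        counts=counts,
        per_annotation=per_annotation,
        n_metacells=matrix.n_metacells,
    )


@dataclass
class MetacellSelection:
    """A thresholded subset of metacells with its annotation breakdown."""

    mask: np.ndarray
    count: int
    per_annotation: dict[str, int]


def select_metacells(
    matrix: MetacellMatrix,
    gene_x: str,
    gene_y: str,
    x_cmp: str,
    x_threshold: float,
    y_cmp: str,
    y_threshold: float,
) -> MetacellSelection:
    """Select metacells by two strict threshold comparisons (">" or "<").

    This is the generic form behind published selections such as
    "Col4a1 > 1 and candidate < 0.1".
    """
    ops = {">": np.greater, "<": np.less}
    if x_cmp not in ops or y_cmp not in ops:
        raise SpecificationError("comparisons must be '>' or '<'")
    mask = ops[x_cmp](matrix.gene(gene_x), x_threshold) & ops[y_cmp](
        matrix.gene(gene_y), y_threshold
    )
    groups = matrix.group_labels.to_numpy()
    per_annotation = {
        str(label): int(((groups == label) & mask).sum())
        for label in pd.unique(groups[mask])
    }
    return MetacellSelection(
        mask=mask, count=int(mask.sum()), per_annotation=per_annotation
    )


def max_over_genes(
    matrix: MetacellMatrix,
    gene_set: list[str],
    exclude: list[str] | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Per-metacell maximum expression over a gene set minus exclusions.

    Returns the per-metacell maxima (over the optionally ``mask``-selected
    metacells, in order) and the number of metacells whose maximum is exactly
    zero — i.e. metacells in which none of the included genes is detected.
    """
    exclude = set(exclude or ())
    included = [g for g in gene_set if g not in exclude]
    if not included:
        raise SpecificationError("gene set is empty after exclusions")
    cols = np.stack([matrix.gene(g) for g in included], axis=1)
    if mask is not None:
        cols = cols[np.asarray(mask, dtype=bool)]
    maxima = cols.max(axis=1) if cols.size else np.empty(0)
    return maxima, int(np.sum(maxima == 0))
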