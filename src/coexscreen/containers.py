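"""Core in-memory containers shared by all pipeline stages.

Three containers travel through the pipeline:

* :class:`ExpressionTable` — a dense genes x samples matrix (bulk compendia,
  time courses, or any wide TSV sheet).
* :class:`CellCounts` — sparse cells x genes raw counts with per-cell
  annotations (single-nucleus data).
* :class:`MetacellMatrix` — metacells x genes normalized expression together
  with the metacell -> member-cell mapping and per-metacell group label.

All containers validate their invariants on construction and never silently
re-sort rows or columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import DomainError, FormatError, GeneLookupError

__all__ = ["ExpressionTable", "CellCounts", "MetacellMatrix"]


def _check_unique(symbols: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for s in symbols:
        if s in seen:
            raise FormatError(f"duplicate {what}: {s!r}")
        seen.add(s)


@dataclass
class ExpressionTable:
    """A genes x samples expression matrix with ordered labels.

    Values are nonnegative (RPKM, microarray intensities, or normalized
    expression); units are whatever the source dataset used and are carried
    opaquely through ``dataset_id``.
    """

    gene_symbols: list[str]
    sample_labels: list[str]
    values: np.ndarray
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.sample_labels = [str(s) for s in self.sample_labels]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_symbols, "gene symbol")
        if self.values.shape != (len(self.gene_symbols), len(self.sample_labels)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_symbols)} genes x {len(self.sample_labels)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        if np.any(self.values < 0):
            raise DomainError("expression values must be nonnegative")
        self._index = {g: i for i, g in enumerate(self.gene_symbols)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def row(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across the ordered samples."""
        try:
            return self.values[self._index[gene]]
        except KeyError:
            raise GeneLookupError(
                f"gene {gene!r} not found in table {self.dataset_id!r}"
            ) from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_symbols, columns=self.sample_labels
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dataset_id: str = "") -> "ExpressionTable":
        return cls(
            gene_symbols=list(frame.index),
            sample_labels=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            dataset_id=dataset_id,
        )


@dataclass
class CellCounts:
    """Sparse raw counts (cells x genes) with a cell-type annotation per cell."""

    cell_ids: list[str]
    gene_symbols: list[str]
    counts: sparse.csr_matrix
    annotations: pd.Series  # index: cell_ids, values: cell-type labels
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        _check_unique(self.cell_ids, "cell id")
        _check_unique(self.gene_symbols, "gene symbol")
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_symbols)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_symbols)} genes"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("counts must be nonnegative integers")
        self.annotations = pd.Series(self.annotations, dtype=object)
        missing = set(self.cell_ids) - set(self.annotations.index)
        if missing:
            raise FormatError(
                f"missing annotation for {len(missing)} cell(s), "
                f"e.g. {sorted(missing)[0]!r}"
            )
        # preserve cell order; drop annotations for cells not in the matrix
        self.annotations = self.annotations.reindex(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_symbols.index(gene)
        except ValueError:
            raise GeneLookupError(
                f"gene {gene!r} not found in counts {self.dataset_id!r}"
            ) from None


@dataclass
class MetacellMatrix:
    """Normalized metacell expression plus membership and group labels.

    ``membership`` maps each metacell id to the ids of its member cells; every
    member of a metacell shares one annotation, recorded in ``group_labels``.
    An empty membership map is allowed for matrices read from disk without a
    sidecar membership file.
    """

    metacell_ids: list[str]
    gene_symbols: list[str]
    expression: np.ndarray  # metacells x genes
    group_labels: pd.Series  # index: metacell_ids
    membership: Mapping[str, frozenset] = field(default_factory=dict)
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.metacell_ids = [str(m) for m in self.metacell_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        _check_unique(self.metacell_ids, "metacell id")
        _check_unique(self.gene_symbols, "gene symbol")
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.shape != (len(self.metacell_ids), len(self.gene_symbols)):
            raise FormatError(
                f"expression shape {self.expression.shape} does not match "
                f"{len(self.metacell_ids)} metacells x {len(self.gene_symbols)} genes"
            )
        self.group_labels = pd.Series(self.group_labels, dtype=object).reindex(
            self.metacell_ids
        )
        if self.group_labels.isna().any():
            raise FormatError("every metacell needs a group label")
        self.membership = {str(k): frozenset(v) for k, v in self.membership.items()}
        self._gene_index = {g: i for i, g in enumerate(self.gene_symbols)}

    @property
    def n_metacells(self) -> int:
        return len(self.metacell_ids)

    def gene(self, gene: str) -> np.ndarray:
        """Expression of one gene across all metacells (in order)."""
        try:
            return self.expression[:, self._gene_index[gene]]
        except KeyError:
            raise GeneLookupError(
                f"gene {gene!r} not found in metacell matrix {self.dataset_id!r}"
            ) from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g, None)
        return list(seen)

    def subset_group(self, group: str) -> "MetacellMatrix":
        mask = (self.group_labels == group).to_numpy()
        ids = [m for m, keep in zip(self.metacell_ids, mask) if keep]
        return MetacellMatrix(
            metacell_ids=ids,
            gene_symbols=list(self.gene_symbols),
            expression=self.expression[mask],
            group_labels=self.group_labels[mask],
            membership={m: self.membership[m] for m in ids if m in self.membership},
            dataset_id=self.dataset_id,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.expression, index=self.metacell_ids, columns=self.gene_symbols
        )
        frame.insert(0, "group", self.group_labels.to_numpy())
        frame.index.name = "metacell_id"
        return frame
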