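"""Readers and writers for every tabular format the pipeline touches.

Formats
-------
* Wide expression TSV: tab-delimited, UTF-8, ``.`` decimal separator, first
  column literally ``gene``, remaining columns sample labels.  This is the
  dialect of FlyBase "download data (TSV)" exports after summarisation.
* Metacell TSV: first columns ``metacell_id`` and ``group``, then one column
  per gene; membership map as a sidecar TSV (``metacell_id``, ``cell_id``).
* Sparse counts: Matrix Market coordinate file (genes x cells, 1-based per
  the standard) with sidecar gene-list and cell-annotation TSVs.
* ImageJ text image: whitespace-delimited numeric matrix, one matrix row per
  line, no header — loadable with File > Import > "Text Image...".

Row and column order is always preserved; read-after-write is the identity
up to the declared numeric precision (writers use full precision by default).
Missing values in expression TSVs are rejected, not imputed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import CellCounts, ExpressionTable, MetacellMatrix
from .errors import FormatError

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_metacell_tsv",
    "write_metacell_tsv",
    "write_text_image",
]

logger = logging.getLogger(__name__)


def _ensure_parent(path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)


def _check_rectangular(path: Path) -> None:
    """Reject ragged rows before handing the file to pandas."""
    with open(path, encoding="utf-8") as handle:
        width = None
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            n = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = n
            elif n != width:
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({n} fields, expected {width})"
                )


def read_expression_tsv(path: str | Path, dataset_id: str = "") -> ExpressionTable:
    """Read a wide gene-by-sample TSV into an :class:`ExpressionTable`.

    Row and column order is preserved from the file.  Duplicate gene symbols,
    ragged rows, and non-numeric or missing cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_rectangular(path)
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: need a gene column plus >=1 sample column")
    gene_col = frame.columns[0]
    genes = frame[gene_col].astype(str).tolist()
    dup = frame[gene_col][frame[gene_col].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate gene symbol {dup.iloc[0]!r}")
    body = frame.iloc[:, 1:]
    try:
        values = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from None
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: missing value for gene {genes[r]!r}, sample "
            f"{body.columns[c]!r}"
        )
    table = ExpressionTable(
        gene_symbols=genes,
        sample_labels=list(body.columns),
        values=values,
        dataset_id=dataset_id or path.stem,
    )
    logger.info("read %s: %d genes x %d samples", path, table.n_genes, table.n_samples)
    return table


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> Path:
    """Write an :class:`ExpressionTable` as a wide TSV (first column ``gene``)."""
    path = Path(path)
    _ensure_parent(path)
    frame = table.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.17g")
    logger.info("wrote %s: %d genes x %d samples", path, table.n_genes, table.n_samples)
    return path


def read_counts_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    annotations_path: str | Path,
    dataset_id: str = "",
) -> CellCounts:
    """Read sparse counts (Matrix Market, genes x cells) plus sidecar TSVs.

    The gene file has one symbol per line; the annotation TSV has columns
    ``cell_id`` and ``cell_type`` in cell order.  Annotations are joined by
    cell id; a cell without an annotation is an error.
    """
    matrix_path, genes_path, annotations_path = (
        Path(matrix_path),
        Path(genes_path),
        Path(annotations_path),
    )
    try:
        mat = scipy_io.mmread(matrix_path)
    except Exception as exc:
        raise FormatError(f"{matrix_path}: not a valid Matrix Market file ({exc})")
    genes = [
        line.strip()
        for line in genes_path.read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    annot = pd.read_csv(annotations_path, sep="\t", dtype=str)
    if not {"cell_id", "cell_type"} <= set(annot.columns):
        raise FormatError(
            f"{annotations_path}: needs 'cell_id' and 'cell_type' columns"
        )
    mat = sparse.csr_matrix(mat)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{matrix_path}: {mat.shape[0]} matrix rows but {len(genes)} genes "
            f"in {genes_path}"
        )
    cells = annot["cell_id"].astype(str).tolist()
    if mat.shape[1] != len(cells):
        raise FormatError(
            f"{matrix_path}: {mat.shape[1]} matrix columns but {len(cells)} cells "
            f"in {annotations_path}"
        )
    counts = CellCounts(
        cell_ids=cells,
        gene_symbols=genes,
        counts=mat.T.tocsr(),
        annotations=pd.Series(
            annot["cell_type"].astype(str).to_numpy(), index=cells, dtype=object
        ),
        dataset_id=dataset_id or matrix_path.stem,
    )
    logger.info(
        "read %s: %d cells x %d genes", matrix_path, counts.n_cells, counts.n_genes
    )
    return counts


def write_counts_mtx(
    counts: CellCounts,
    matrix_path: str | Path,
    genes_path: str | Path,
    annotations_path: str | Path,
) -> None:
    """Write counts as Matrix Market (genes x cells) plus sidecar TSVs."""
    matrix_path, genes_path, annotations_path = (
        Path(matrix_path),
        Path(genes_path),
        Path(annotations_path),
    )
    for p in (matrix_path, genes_path, annotations_path):
        _ensure_parent(p)
    mat = counts.counts.T.tocoo()
    scipy_io.mmwrite(matrix_path, mat, field="integer")
    genes_path.write_text("\n".join(counts.gene_symbols) + "\n", encoding="utf-8")
    pd.DataFrame(
        {"cell_id": counts.cell_ids, "cell_type": counts.annotations.to_numpy()}
    ).to_csv(annotations_path, sep="\t", index=False)
    logger.info(
        "wrote %s: %d cells x %d genes", matrix_path, counts.n_cells, counts.n_genes
    )


def read_metacell_tsv(
    path: str | Path,
    membership_path: str | Path | None = None,
    dataset_id: str = "",
) -> MetacellMatrix:
    """Read a metacell matrix TSV (``metacell_id``, ``group``, gene columns)."""
    path = Path(path)
    _check_rectangular(path)
    frame = pd.read_csv(
        path, sep="\t", header=0, dtype={0: str}, float_precision="round_trip"
    )
    required = ["metacell_id", "group"]
    if list(frame.columns[:2]) != required:
        raise FormatError(f"{path}: first columns must be {required}")
    membership = {}
    if membership_path is not None:
        mem = pd.read_csv(membership_path, sep="\t", dtype=str)
        if not {"metacell_id", "cell_id"} <= set(mem.columns):
            raise FormatError(
                f"{membership_path}: needs 'metacell_id' and 'cell_id' columns"
            )
        membership = {
            mc: frozenset(grp["cell_id"])
            for mc, grp in mem.groupby("metacell_id", sort=False)
        }
    ids = frame["metacell_id"].astype(str).tolist()
    matrix = MetacellMatrix(
        metacell_ids=ids,
        gene_symbols=list(frame.columns[2:]),
        expression=frame.iloc[:, 2:].to_numpy(dtype=float),
        group_labels=pd.Series(
            frame["group"].astype(str).to_numpy(), index=ids, dtype=object
        ),
        membership=membership,
        dataset_id=dataset_id or path.stem,
    )
    logger.info(
        "read %s: %d metacells x %d genes",
        path,
        matrix.n_metacells,
        len(matrix.gene_symbols),
    )
    return matrix


def write_metacell_tsv(
    matrix: MetacellMatrix,
    path: str | Path,
    membership_path: str | Path | None = None,
) -> Path:
    """Write a metacell matrix TSV, optionally with a membership sidecar."""
    path = Path(path)
    _ensure_parent(path)
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    if membership_path is not None:
        membership_path = Path(membership_path)
        _ensure_parent(membership_path)
        rows = [
            {"metacell_id": mc, "cell_id": cell}
            for mc in matrix.metacell_ids
            for cell in sorted(matrix.membership.get(mc, ()))
        ]
        pd.DataFrame(rows, columns=["metacell_id", "cell_id"]).to_csv(
            membership_path, sep="\t", index=False
        )
    logger.info(
        "wrote %s: %d metacells x %d genes",
        path,
        matrix.n_metacells,
        len(matrix.gene_symbols),
    )
    return path


def write_text_image(
    matrix: np.ndarray, path: str | Path, fill: float | None = None
) -> Path:
    """Write a numeric matrix as an ImageJ-importable text image.

    Space-separated ``%g`` values, one matrix row per line, no header.  NaN
    entries raise unless ``fill`` is given, in which case they are replaced.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise FormatError("text image requires a 2-D matrix")
    if np.isnan(matrix).any():
        if fill is None:
            raise FormatError(
                "matrix contains NaN; pass fill=<value> to write a text image"
            )
        matrix = np.where(np.isnan(matrix), fill, matrix)
    if not np.all(np.isfinite(matrix)):
        raise FormatError("text image requires finite values")
    path = Path(path)
    _ensure_parent(path)
    with open(path, "w", encoding="utf-8") as handle:
        for row in matrix:
            handle.write(" ".join("%g" % v for v in row) + "\n")
    logger.info("wrote text image %s: %d x %d", path, *matrix.shape)
    return path
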