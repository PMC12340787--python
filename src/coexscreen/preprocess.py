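"""Single-cell QC, normalisation, feature selection, PCA and metacells.

The stages mirror a standard droplet/single-nucleus workflow: cells are kept
when their detected-gene count falls within configured bounds; counts are
normalised per cell to a fixed total (counts-per-10k by default) and
ln(1+x)-transformed; genes detected in fewer than a configured fraction of
cells are dropped; the most variable genes are selected by binned
standardized dispersion; cells are embedded with PCA on per-gene z-scores
clipped at +/-10.

Metacells are then built per annotation group: a seed cell plus its k-1
nearest neighbours in the embedding (Euclidean, within-group) form a
candidate metacell, which is accepted if it shares at most ``max_shared``
member cells with every previously accepted metacell.  Metacell expression
is the per-gene mean of members' log-normalised expression, re-normalised on
the linear scale and re-logged (switchable).

Defaults follow the convention of k = 25 member cells with at most 10 shared
between any two metacells, 2000 variable genes, 50 principal components, and
a 5%-of-cells gene-prevalence floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA

from .containers import CellCounts, MetacellMatrix
from .errors import DomainError, EmptyResultError, SpecificationError

__all__ = [
    "PreprocessParams",
    "MetacellParams",
    "qc_filter",
    "lognormalize",
    "gene_prevalence_filter",
    "select_hvg",
    "scale_genes",
    "pca_embed",
    "build_metacells",
    "run_preprocessing",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Quality-control and normalisation settings.

    ``max_genes_per_cell`` defaults to 2500, the midpoint of the customary
    per-tissue range of 2000-3500 detected genes; tissues differ, so it is a
    plain knob rather than a fixed truth.
    """

    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 2500
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: int = 50
    min_cell_fraction_per_gene: float = 0.05

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise SpecificationError("min_genes_per_cell must be < max_genes_per_cell")
        if not 0 < self.min_cell_fraction_per_gene < 1:
            raise SpecificationError("min_cell_fraction_per_gene must be in (0, 1)")
        if self.scale_factor <= 0 or self.n_hvg < 1 or self.n_pcs < 1:
            raise SpecificationError("scale_factor, n_hvg and n_pcs must be positive")


@dataclass
class MetacellParams:
    """KNN metacell aggregation settings (k member cells, overlap cap)."""

    k: int = 25
    max_shared: int = 10
    seed: int = 0
    max_attempts_per_group: int = 5000
    renormalize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise SpecificationError("k must be >= 1")
        if not 0 <= self.max_shared < self.k:
            raise SpecificationError("max_shared must satisfy 0 <= max_shared < k")
        if self.max_attempts_per_group < 1:
            raise SpecificationError("max_attempts_per_group must be >= 1")


def qc_filter(counts: CellCounts, params: PreprocessParams) -> CellCounts:
    """Keep cells whose detected-gene count lies in [min, max] inclusive."""
    detected = np.diff(counts.counts.indptr)  # nonzero entries per cell (CSR)
    keep = (detected >= params.min_genes_per_cell) & (
        detected <= params.max_genes_per_cell
    )
    n_removed = int((~keep).sum())
    if not keep.any():
        raise EmptyResultError(
            f"qc_filter removed all {counts.n_cells} cells "
            f"(bounds [{params.min_genes_per_cell}, {params.max_genes_per_cell}])"
        )
    logger.info("qc_filter: removed %d of %d cells", n_removed, counts.n_cells)
    idx = np.where(keep)[0]
    cell_ids = [counts.cell_ids[i] for i in idx]
    return CellCounts(
        cell_ids=cell_ids,
        gene_symbols=list(counts.gene_symbols),
        counts=counts.counts[idx],
        annotations=counts.annotations.iloc[idx],
        dataset_id=counts.dataset_id,
    )


def lognormalize(counts: CellCounts, scale_factor: float = 10_000.0) -> np.ndarray:
    """ln(1 + count / cell_total * scale_factor), dense cells x genes.

    A cell with zero total counts is an error: run :func:`qc_filter` first.
    """
    totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = counts.cell_ids[int(np.argmax(totals == 0))]
        raise DomainError(
            f"cell {bad!r} has zero total counts; apply qc_filter before "
            "normalisation"
        )
    mat = counts.counts.multiply(scale_factor / totals[:, None]).toarray()
    return np.log1p(mat)


def gene_prevalence_filter(
    counts: CellCounts, min_cell_fraction: float = 0.05
) -> CellCounts:
    """Keep genes detected (nonzero) in >= ceil(fraction * n_cells) cells."""
    if not 0 < min_cell_fraction < 1:
        raise SpecificationError("min_cell_fraction must be in (0, 1)")
    n_detected = np.asarray((counts.counts > 0).sum(axis=0)).ravel()
    floor = int(np.ceil(min_cell_fraction * counts.n_cells))
    keep = n_detected >= floor
    logger.info(
        "gene_prevalence_filter: kept %d of %d genes (floor %d cells)",
        int(keep.sum()),
        counts.n_genes,
        floor,
    )
    idx = np.where(keep)[0]
    return CellCounts(
        cell_ids=list(counts.cell_ids),
        gene_symbols=[counts.gene_symbols[i] for i in idx],
        counts=counts.counts[:, idx].tocsr(),
        annotations=counts.annotations,
        dataset_id=counts.dataset_id,
    )


def select_hvg(
    normalized: np.ndarray,
    gene_symbols: list[str],
    n_hvg: int,
    n_bins: int = 20,
) -> list[int]:
    """Top ``n_hvg`` genes by binned standardized dispersion.

    Genes are binned into ``n_bins`` equal-frequency bins of mean
    log-normalised expression; within each bin the dispersion
    (variance/mean of the exponentiated expression, the classic definition)
    is z-scored, and the genes with the largest standardized dispersion are
    selected.  Ties are broken by gene input order.  Returns gene indices in
    input order.
    """
    n_genes = normalized.shape[1]
    if n_hvg > n_genes:
        raise SpecificationError(f"n_hvg={n_hvg} exceeds gene count {n_genes}")
    if n_hvg == n_genes:
        return list(range(n_genes))
    # classic dispersion on the linear scale of expm1(x)
    linear = np.expm1(normalized)
    mean = linear.mean(axis=0)
    var = linear.var(axis=0, ddof=1) if normalized.shape[0] > 1 else np.zeros(n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)

    n_bins = min(n_bins, max(1, n_genes))
    ranks = pd.Series(mean).rank(method="first").to_numpy()
    bins = np.floor((ranks - 1) * n_bins / n_genes).astype(int)
    score = np.zeros(n_genes)
    for b in np.unique(bins):
        members = bins == b
        d = dispersion[members]
        sd = d.std(ddof=0)
        score[members] = (d - d.mean()) / sd if sd > 0 else 0.0
    # a constant gene is never "variable", whatever its bin's statistics
    score[np.ptp(normalized, axis=0) == 0] = -np.inf
    order = np.lexsort((np.arange(n_genes), -score))
    return sorted(order[:n_hvg].tolist())


def scale_genes(matrix: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Z-score each gene (column) and clip at +/-clip; constant genes -> 0."""
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return np.clip((matrix - mean) / sd, -clip, clip)


def pca_embed(scaled: np.ndarray, n_pcs: int) -> np.ndarray:
    """PCA scores (cells x n_pcs), variance-ordered, deterministic sign.

    The input must already be per-gene z-scored (see :func:`scale_genes`).
    Each component is oriented so its largest-magnitude gene loading is
    positive.
    """
    n_cells, n_genes = scaled.shape
    if n_pcs > min(n_cells, n_genes):
        raise SpecificationError(
            f"n_pcs={n_pcs} exceeds min(cells, genes)={min(n_cells, n_genes)}"
        )
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(scaled)
    # deterministic sign convention independent of the solver's own flip
    for j in range(n_pcs):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] *= -1
    return scores


def build_metacells(
    embedding: np.ndarray,
    normalized: np.ndarray,
    gene_symbols: list[str],
    cell_ids: list[str],
    annotations: pd.Series,
    params: MetacellParams,
    scale_factor: float = 10_000.0,
    dataset_id: str = "",
) -> MetacellMatrix:
    """Aggregate cells into metacells per annotation group.

    Per group with at least k cells (smaller groups are skipped with a log
    line): seed cells are drawn without replacement in a seeded random order,
    cycling; each candidate metacell is the seed plus its k-1 nearest
    within-group neighbours in embedding space (Euclidean, ties broken by
    cell input order); the candidate is accepted iff it shares at most
    ``max_shared`` members with every accepted metacell.  The group stops
    after ``max_attempts_per_group`` consecutive rejections (or after a full
    cycle of rejections, whichever is smaller — once every seed has been
    rejected against a fixed accepted set, no further acceptance is
    possible).

    Metacell expression is the per-gene mean of the members' log-normalised
    expression; with ``params.renormalize`` (the default) the mean is mapped
    back to the linear scale with expm1, rescaled to ``scale_factor`` total
    per metacell, and re-logged with log1p.
    """
    annotations = pd.Series(annotations, dtype=object)
    groups: dict[str, np.ndarray] = {}
    for label in pd.unique(annotations.to_numpy()):
        groups[str(label)] = np.where((annotations == label).to_numpy())[0]

    rng = np.random.default_rng(params.seed)
    meta_ids: list[str] = []
    meta_expr: list[np.ndarray] = []
    meta_groups: list[str] = []
    membership: dict[str, frozenset] = {}

    for label, idx in groups.items():
        n = idx.size
        if n < params.k:
            logger.info(
                "build_metacells: skipping group %r (%d cells < k=%d)",
                label,
                n,
                params.k,
            )
            continue
        emb = embedding[idx]
        # within-group pairwise distances; ties broken by cell input order
        d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2)
        neighbour_order = np.argsort(d2, axis=1, kind="stable")
        accepted: list[np.ndarray] = []  # boolean membership masks over group
        order = rng.permutation(n)
        pos = 0
        consecutive_rejections = 0
        stop_at = min(params.max_attempts_per_group, n)
        while consecutive_rejections < stop_at:
            if pos == n:
                order = rng.permutation(n)
                pos = 0
            seed_cell = order[pos]
            pos += 1
            row = neighbour_order[seed_cell]
            nearest = row[row != seed_cell][: params.k - 1]
            members = np.concatenate(([seed_cell], nearest))
            mask = np.zeros(n, dtype=bool)
            mask[members] = True
            if all((mask & prev).sum() <= params.max_shared for prev in accepted):
                accepted.append(mask)
                consecutive_rejections = 0
                mc_id = f"{label}_mc{len(accepted)}"
                member_idx = idx[mask]
                expr = normalized[member_idx].mean(axis=0)
                if params.renormalize:
                    linear = np.expm1(expr)
                    total = linear.sum()
                    if total > 0:
                        linear = linear * (scale_factor / total)
                    expr = np.log1p(linear)
                meta_ids.append(mc_id)
                meta_expr.append(expr)
                meta_groups.append(label)
                membership[mc_id] = frozenset(cell_ids[i] for i in member_idx)
            else:
                consecutive_rejections += 1
        logger.info(
            "build_metacells: group %r -> %d metacells from %d cells",
            label,
            len(accepted),
            n,
        )

    if not meta_ids:
        raise EmptyResultError("no group had enough cells to form a metacell")
    return MetacellMatrix(
        metacell_ids=meta_ids,
        gene_symbols=list(gene_symbols),
        expression=np.vstack(meta_expr),
        group_labels=pd.Series(meta_groups, index=meta_ids, dtype=object),
        membership=membership,
        dataset_id=dataset_id,
    )


def run_preprocessing(
    counts: CellCounts,
    pparams: PreprocessParams,
    mparams: MetacellParams,
) -> MetacellMatrix:
    """QC -> prevalence filter -> normalise -> HVG -> PCA -> metacells.

    The metacell expression matrix keeps all prevalence-passing genes (the
    variable-gene subset is used only for the embedding), so downstream
    network and quadrant analyses can address genes that are expressed but
    not highly variable.
    """
    counts = qc_filter(counts, pparams)
    counts = gene_prevalence_filter(counts, pparams.min_cell_fraction_per_gene)
    normalized = lognormalize(counts, pparams.scale_factor)
    n_hvg = min(pparams.n_hvg, counts.n_genes)
    hvg_idx = select_hvg(normalized, counts.gene_symbols, n_hvg)
    scaled = scale_genes(normalized[:, hvg_idx])
    n_pcs = min(pparams.n_pcs, min(scaled.shape))
    embedding = pca_embed(scaled, n_pcs)
    return build_metacells(
        embedding,
        normalized,
        counts.gene_symbols,
        counts.cell_ids,
        counts.annotations,
        mparams,
        scale_factor=pparams.scale_factor,
        dataset_id=counts.dataset_id,
    )
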