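"""Weighted co-expression network construction per cell-type group.

The construction follows the classic weighted-network recipe: Pearson
correlations between genes across metacells are mapped to a signed adjacency
``a_ij = ((1 + cor_ij)/2)^beta`` (or ``|cor_ij|^beta`` unsigned), with the
soft power beta chosen as the lowest candidate whose network is approximately
scale-free (signed R^2 of the log-log connectivity-frequency regression at or
above a fit threshold, 0.8 by default).  Adjacency is converted to the
topological overlap matrix (TOM), which credits shared neighbours; modules
are the clusters of an average-linkage tree on 1-TOM under a static cut,
with undersized clusters relabelled "unassigned".  Each module is summarised
by its eigengene (first principal component of the z-scored member matrix),
and every gene's module membership strength is its kME — the correlation of
the gene with each module eigengene.

The static tree cut (a fixed fraction of the maximum merge height plus a
minimum module size) replaces dynamic tree cutting: it is fully
deterministic and specifiable, and ``detect_modules`` is pluggable for
callers who want a different cutter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DomainError, SpecificationError

__all__ = [
    "NetworkParams",
    "correlation_matrix",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "fit_connectivity_distribution",
    "select_soft_power",
    "fit_group_networks",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "kme",
    "CoexpressionNetwork",
    "CoexpressionNetworkResults",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class NetworkParams:
    """Network construction settings (soft-power grid, cut, module floor)."""

    candidate_powers: list[int] = field(default_factory=lambda: list(range(1, 31)))
    fit_threshold: float = 0.8
    min_module_size: int = 10
    cut_height_fraction: float = 0.99
    signed: bool = True

    def __post_init__(self) -> None:
        if not self.candidate_powers or min(self.candidate_powers) < 1:
            raise SpecificationError("candidate powers must be positive integers")
        if not 0 < self.fit_threshold < 1:
            raise SpecificationError("fit_threshold must be in (0, 1)")
        if not 0 < self.cut_height_fraction <= 1:
            raise SpecificationError("cut_height_fraction must be in (0, 1]")
        if self.min_module_size < 1:
            raise SpecificationError("min_module_size must be >= 1")


def correlation_matrix(expr: np.ndarray) -> np.ndarray:
    """Gene-gene Pearson correlations (expr: metacells x genes, no constants)."""
    sd = expr.std(axis=0)
    if np.any(sd == 0):
        raise DomainError("zero-variance gene in correlation matrix input")
    cor = np.corrcoef(expr, rowvar=False)
    return np.clip(cor, -1.0, 1.0)


def adjacency(expr: np.ndarray, beta: int, signed: bool = True) -> np.ndarray:
    """Soft-thresholded adjacency with zero diagonal.

    Signed: ``((1 + cor)/2)^beta`` — perfect anticorrelation maps to 0,
    perfect correlation to 1, independence to ``0.5^beta``.  Unsigned:
    ``|cor|^beta``.
    """
    if beta < 1:
        raise SpecificationError("beta must be >= 1")
    cor = correlation_matrix(expr)
    adj = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Per-gene connectivity k_i = sum_{j != i} a_ij (diagonal already 0)."""
    return adj.sum(axis=1)


def scale_free_fit(
    expr: np.ndarray, power: int, signed: bool = True, n_bins: int = 10
) -> tuple[float, float]:
    """Scale-free topology fit statistic at one soft power.

    Connectivities are binned into ``n_bins`` equal-width bins (empty bins
    dropped); log10(frequency) is regressed on log10(mean connectivity)
    across bins.  Returns ``(signed_r2, mean_connectivity)`` where
    ``signed_r2 = -sign(slope) * R^2`` so a decreasing frequency-connectivity
    law scores positively.  Fewer than 3 usable bins leaves the fit
    undefined (NaN).
    """
    if expr.shape[1] < 10:
        raise SpecificationError("scale-free fit needs at least 10 genes")
    k = connectivity(adjacency(expr, power, signed=signed))
    return fit_connectivity_distribution(k, n_bins=n_bins), float(k.mean())


def fit_connectivity_distribution(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the binned log-log connectivity-frequency regression.

    Used by :func:`scale_free_fit`; exposed so a connectivity vector from
    any source can be scored directly.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq = []
    log_k = []
    for b in range(n_bins):
        members = which == b
        if not members.any():
            continue
        mk = k[members].mean()
        if mk <= 0:
            continue
        log_freq.append(np.log10(members.sum() / k.size))
        log_k.append(np.log10(mk))
    if len(log_k) < 3 or np.ptp(log_k) == 0:
        return float("nan")
    fit = stats.linregress(log_k, log_freq)
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def select_soft_power(
    expr: np.ndarray, params: NetworkParams
) -> tuple[int, pd.DataFrame, bool]:
    """Lowest candidate power meeting the fit threshold.

    Returns ``(beta, fit_table, warning)``; when no power qualifies, the
    power with maximal signed R^2 is returned with ``warning=True``.  All
    fits undefined is an error.
    """
    rows = []
    for power in params.candidate_powers:
        r2, mean_k = scale_free_fit(expr, power, signed=params.signed)
        rows.append((power, r2, mean_k))
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_connectivity"])
    defined = table.dropna(subset=["signed_r2"])
    if defined.empty:
        raise DomainError("scale-free fit undefined at every candidate power")
    meeting = defined[defined["signed_r2"] >= params.fit_threshold]
    if not meeting.empty:
        return int(meeting["power"].iloc[0]), table, False
    best = defined.loc[defined["signed_r2"].idxmax(), "power"]
    logger.warning(
        "no candidate power reached fit %.2f; falling back to argmax power %d",
        params.fit_threshold,
        int(best),
    )
    return int(best), table, True


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for
    i != j (the shared-neighbour sum excludes u in {i, j} because the
    diagonal is zero), and ``TOM_ii = 1``.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise DomainError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise DomainError("adjacency must be symmetric")
    if np.any(adj < 0) or np.any(adj > 1):
        raise DomainError("adjacency entries must lie in [0, 1]")
    adj = adj.copy()
    np.fill_diagonal(adj, 0.0)
    k = connectivity(adj)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray, gene_symbols: list[str], params: NetworkParams
) -> pd.Series:
    """Static-cut average-linkage modules on the 1-TOM dissimilarity.

    The tree is cut at ``cut_height_fraction`` of the maximum merge height;
    clusters smaller than ``min_module_size`` become "unassigned"; surviving
    modules are named M1, M2, ... by decreasing size (ties by first member's
    input position).
    """
    n = len(gene_symbols)
    if tom.shape != (n, n):
        raise DomainError("TOM shape does not match gene list")
    if n < params.min_module_size:
        return pd.Series([UNASSIGNED] * n, index=gene_symbols, dtype=object)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(np.clip((dissim + dissim.T) / 2.0, 0.0, None), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    max_height = link[:, 2].max()
    cut = params.cut_height_fraction * max_height
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")

    sizes: dict[int, int] = {}
    first_pos: dict[int, int] = {}
    for pos, lab in enumerate(labels):
        sizes[lab] = sizes.get(lab, 0) + 1
        first_pos.setdefault(lab, pos)
    kept = [lab for lab, s in sizes.items() if s >= params.min_module_size]
    kept.sort(key=lambda lab: (-sizes[lab], first_pos[lab]))
    rename = {lab: f"M{i + 1}" for i, lab in enumerate(kept)}
    assigned = [rename.get(lab, UNASSIGNED) for lab in labels]
    return pd.Series(assigned, index=gene_symbols, dtype=object)


def module_eigengene(
    expr: np.ndarray, gene_symbols: list[str], assignment: pd.Series
) -> pd.DataFrame:
    """Module eigengenes: first PC scores of each module's z-scored members.

    Each eigengene is unit-norm over metacells and oriented so its mean
    correlation with the module's member genes is nonnegative.  Columns are
    module labels (``unassigned`` excluded), rows metacells.
    """
    modules = [m for m in pd.unique(assignment.to_numpy()) if m != UNASSIGNED]
    modules.sort(key=lambda m: int(m[1:]) if m[1:].isdigit() else 1_000_000)
    index = {g: i for i, g in enumerate(gene_symbols)}
    eigengenes = {}
    for module in modules:
        members = [g for g in assignment.index if assignment[g] == module]
        sub = expr[:, [index[g] for g in members]]
        z = (sub - sub.mean(axis=0)) / np.where(sub.std(axis=0) > 0, sub.std(axis=0), 1)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = u[:, 0]
        cors = np.array([_safe_corr(eig, z[:, j]) for j in range(z.shape[1])])
        if np.nanmean(cors) < 0:
            eig = -eig
        eigengenes[module] = eig
    return pd.DataFrame(eigengenes)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def kme(
    expr: np.ndarray, gene_symbols: list[str], eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """Eigengene connectivity: corr(gene, module eigengene), genes x modules.

    Zero-variance genes get NaN entries.
    """
    if not eigengenes.empty and len(eigengenes) != expr.shape[0]:
        raise DomainError("eigengene length must equal metacell count")
    out = np.full((len(gene_symbols), eigengenes.shape[1]), np.nan)
    for j, module in enumerate(eigengenes.columns):
        eig = eigengenes[module].to_numpy()
        for i in range(len(gene_symbols)):
            out[i, j] = _safe_corr(expr[:, i], eig)
    return pd.DataFrame(out, index=gene_symbols, columns=eigengenes.columns)


@dataclass
class CoexpressionNetworkResults:
    """One group's co-expression network: power, modules, eigengenes, kME."""

    group_label: str
    beta: int
    power_warning: bool
    fit_table: pd.DataFrame
    assignment: pd.Series  # gene -> module label or "unassigned"
    eigengenes: pd.DataFrame  # metacells x modules
    kme: pd.DataFrame  # genes x modules
    dropped_genes: list[str]

    def module_of(self, gene: str) -> str:
        return str(self.assignment[gene])

    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def summary(self) -> str:
        sizes = self.assignment.value_counts()
        lines = [
            f"Co-expression network: group {self.group_label!r}",
            f"  soft power beta = {self.beta}"
            + ("  (fit threshold not reached; argmax fallback)" if self.power_warning else ""),
            f"  genes: {len(self.assignment)}  modules: {len(self.modules())}"
            + (f"  dropped (zero variance): {len(self.dropped_genes)}" if self.dropped_genes else ""),
        ]
        for module in self.modules():
            lines.append(f"    {module}: {int(sizes.get(module, 0))} genes")
        lines.append(f"    {UNASSIGNED}: {int(sizes.get(UNASSIGNED, 0))} genes")
        return "\n".join(lines)


class CoexpressionNetwork:
    """Model object building one group's weighted co-expression network.

    Parameters
    ----------
    expr:
        Metacells x genes expression frame for one cell-type group.
    group_label:
        Annotation label carried into the results.
    params:
        :class:`NetworkParams`; defaults follow the signed-network
        convention with a 0.8 scale-free fit threshold.
    module_detector:
        Optional replacement for :func:`detect_modules` with the same
        signature, for alternative tree cutters.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        group_label: str = "",
        params: NetworkParams | None = None,
        module_detector=None,
    ) -> None:
        self.expr_frame = expr
        self.group_label = group_label
        self.params = params or NetworkParams()
        self.module_detector = module_detector or detect_modules

    def fit(self) -> CoexpressionNetworkResults:
        frame = self.expr_frame
        values = frame.to_numpy(dtype=float)
        sd = values.std(axis=0)
        keep = sd > 0
        dropped = [g for g, ok in zip(frame.columns, keep) if not ok]
        if dropped:
            logger.info(
                "group %r: removing %d zero-variance gene(s) before network "
                "construction",
                self.group_label,
                len(dropped),
            )
        genes = [g for g, ok in zip(frame.columns, keep) if ok]
        expr = values[:, keep]
        if len(genes) < 10:
            raise SpecificationError(
                f"group {self.group_label!r}: need >= 10 varying genes, "
                f"have {len(genes)}"
            )
        beta, fit_table, warning = select_soft_power(expr, self.params)
        adj = adjacency(expr, beta, signed=self.params.signed)
        tom = topological_overlap(adj)
        assignment = self.module_detector(tom, genes, self.params)
        # dropped genes stay in the universe as unassigned
        full = pd.Series(UNASSIGNED, index=list(frame.columns), dtype=object)
        full[assignment.index] = assignment
        eigengenes = module_eigengene(expr, genes, assignment)
        kme_table = kme(expr, genes, eigengenes)
        return CoexpressionNetworkResults(
            group_label=self.group_label,
            beta=beta,
            power_warning=warning,
            fit_table=fit_table,
            assignment=full,
            eigengenes=eigengenes,
            kme=kme_table,
            dropped_genes=dropped,
        )


def fit_group_networks(
    matrix, params: NetworkParams | None = None, min_metacells: int = 15
) -> dict[str, CoexpressionNetworkResults]:
    """Fit one network per metacell group with at least ``min_metacells``."""
    results = {}
    for group in matrix.groups():
        sub = matrix.subset_group(group)
        if sub.n_metacells < min_metacells:
            logger.info(
                "skipping group %r: %d metacells < %d",
                group,
                sub.n_metacells,
                min_metacells,
            )
            continue
        frame = pd.DataFrame(
            sub.expression, index=sub.metacell_ids, columns=sub.gene_symbols
        )
        results[group] = CoexpressionNetwork(frame, group, params).fit()
    return results
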