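"""Synthetic expression data with planted co-expression ground truth.

Three generators cover the pipeline's three input kinds:

* :func:`make_bulk_table` — a bulk compendium (genes x samples) in which one
  planted partner gene tracks a reference gene at a calibrated Pearson
  correlation while every other gene is independent right-skewed noise.
  This emulates the structure of the FlyBase high-throughput compendia used
  in a reference-gene correlation screen (reference = a collagen IV subunit,
  candidates = the ~26 prolyl-4-hydroxylase-alpha-related genes).
* :func:`make_cell_counts` — single-nucleus-style negative-binomial counts
  over a few cell types, with a planted co-expression module (the substrate
  pair ``Col4a1``/``vkg`` plus one candidate enzyme and optional extras)
  driven by a per-cell log-normal latent factor, and independent decoy
  candidates whose baselines match the planted candidate so expression level
  alone cannot separate them.
* :func:`make_assignment_fixture` — per-group gene -> module assignments with
  a known number of candidate/substrate co-assignments, for testing the
  co-occurrence counting and permutation machinery directly.

All generators are deterministic given the spec seed.  The global seed is
expanded into per-stage child streams with fixed offsets so that, e.g.,
adding genes does not perturb cell-type sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import CellCounts, ExpressionTable
from .errors import SpecificationError

__all__ = [
    "BulkSimSpec",
    "ScSimSpec",
    "CellTypeSpec",
    "AssignmentFixture",
    "make_bulk_table",
    "make_cell_counts",
    "make_assignment_fixture",
    "default_sc_spec",
]

# fixed offsets expanding the global seed into independent child streams
_OFFSET_CELL_TYPES = 1
_OFFSET_LATENT = 2
_OFFSET_COUNTS = 3
_OFFSET_BULK_PAIR = 4
_OFFSET_BULK_NOISE = 5
_OFFSET_FIXTURE = 6

_MOD = 2**31


def _child_rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) * 8 + offset) % _MOD)


@dataclass
class BulkSimSpec:
    """Specification of a bulk compendium with one planted co-expressed pair.

    ``target_correlation`` is the desired linear-scale Pearson correlation of
    the reference/partner pair; ``noise_sd`` is the log-scale standard
    deviation of every gene (RPKM-like data are right-skewed, so genes are
    generated as exponentiated Gaussians).
    """

    n_genes: int = 28
    n_samples: int = 25
    reference_gene: str = "Col4a1"
    planted_partner: str = "PH4aEFB"
    target_correlation: float = 0.8
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise SpecificationError("need at least 2 genes")
        if self.n_samples < 3:
            raise SpecificationError("need at least 3 samples")
        if self.planted_partner == self.reference_gene:
            raise SpecificationError("planted partner must differ from reference")
        if not 0.0 <= self.target_correlation <= 1.0:
            raise SpecificationError("target_correlation must be in [0, 1]")
        if self.noise_sd <= 0:
            raise SpecificationError("noise_sd must be positive")

    def gene_list(self) -> list[str]:
        """Reference, partner, then decoy candidates named CG1, CG2, ..."""
        decoys = [f"CG{i + 1}" for i in range(self.n_genes - 2)]
        return [self.reference_gene, self.planted_partner, *decoys]


def _lognormal_rho(target_r: float, sigma: float) -> float:
    """Log-scale Gaussian correlation reproducing a linear-scale Pearson r.

    For a bivariate lognormal with equal log-scale variance sigma^2 and
    log-scale correlation rho, the linear-scale correlation is
    (exp(rho sigma^2) - 1) / (exp(sigma^2) - 1); invert that in closed form.
    """
    if target_r <= 0.0:
        return 0.0
    s2 = sigma * sigma
    rho = math.log1p(target_r * math.expm1(s2)) / s2
    return min(rho, 1.0)


def make_bulk_table(spec: BulkSimSpec) -> ExpressionTable:
    """Generate a bulk expression table with the planted pair correlated.

    The reference and partner are exponentiated correlated Gaussians whose
    log-scale correlation is calibrated so the linear-scale Pearson r
    approximates ``target_correlation``; all other genes are independent
    lognormal noise.  Deterministic given ``spec.seed``.
    """
    genes = spec.gene_list()
    rng_pair = _child_rng(spec.seed, _OFFSET_BULK_PAIR)
    rng_noise = _child_rng(spec.seed, _OFFSET_BULK_NOISE)

    rho = _lognormal_rho(spec.target_correlation, spec.noise_sd)
    # shared positive latent factor construction: z_partner mixes the
    # reference's Gaussian with an independent one at weight sqrt(rho)
    z_ref = rng_pair.standard_normal(spec.n_samples)
    z_ind = rng_pair.standard_normal(spec.n_samples)
    z_par = rho * z_ref + math.sqrt(max(0.0, 1.0 - rho * rho)) * z_ind

    values = np.empty((spec.n_genes, spec.n_samples))
    values[0] = np.exp(spec.noise_sd * z_ref)
    values[1] = np.exp(spec.noise_sd * z_par)
    if spec.n_genes > 2:
        z_noise = rng_noise.standard_normal((spec.n_genes - 2, spec.n_samples))
        values[2:] = np.exp(spec.noise_sd * z_noise)
    # per-gene baselines spread over a few orders of magnitude, like RPKM
    baselines = 10.0 ** rng_noise.uniform(0.0, 3.0, size=spec.n_genes)
    values *= baselines[:, None]

    return ExpressionTable(
        gene_symbols=genes,
        sample_labels=[f"sample_{i + 1}" for i in range(spec.n_samples)],
        values=values,
        dataset_id=f"bulk_sim_seed{spec.seed}",
    )


@dataclass
class CellTypeSpec:
    """One simulated cell type: label, mixing proportion, per-gene baseline."""

    label: str
    proportion: float
    baseline: np.ndarray  # per-gene mean counts

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.proportion <= 0:
            raise SpecificationError(f"cell type {self.label!r}: proportion <= 0")
        if np.any(self.baseline < 0):
            raise SpecificationError(f"cell type {self.label!r}: negative baseline")


@dataclass
class ScSimSpec:
    """Specification of single-cell counts with a planted co-expression module.

    Module genes share a per-cell latent factor: their negative-binomial mean
    is multiplied by exp(latent_effect * z_cell) with z_cell standard normal.
    The first ``n_decoy_candidates`` non-module genes are decoy candidates
    whose baselines are matched to the planted candidate's.
    """

    n_cells: int = 2000
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    n_genes: int = 120
    module_genes: list[str] = field(default_factory=list)
    latent_effect: float = 1.5
    nb_dispersion: float = 2.0
    n_decoy_candidates: int = 25
    seed: int = 0
    gene_symbols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cell_types:
            raise SpecificationError("at least one cell type is required")
        total = sum(ct.proportion for ct in self.cell_types)
        if abs(total - 1.0) > 1e-8:
            raise SpecificationError(f"cell-type proportions sum to {total}, not 1")
        if self.nb_dispersion <= 0:
            raise SpecificationError("nb_dispersion must be positive")
        if self.latent_effect < 0:
            raise SpecificationError("latent_effect must be nonnegative")
        if not self.gene_symbols:
            raise SpecificationError("gene_symbols must be provided")
        if len(self.gene_symbols) != self.n_genes:
            raise SpecificationError("gene_symbols length must equal n_genes")
        unknown = set(self.module_genes) - set(self.gene_symbols)
        if unknown:
            raise SpecificationError(f"module genes not in gene list: {sorted(unknown)}")
        for ct in self.cell_types:
            if ct.baseline.shape != (self.n_genes,):
                raise SpecificationError(
                    f"cell type {ct.label!r}: baseline length "
                    f"{ct.baseline.shape} != n_genes {self.n_genes}"
                )

    @property
    def substrate_pair(self) -> tuple[str, str]:
        return (self.module_genes[0], self.module_genes[1])

    @property
    def planted_candidate(self) -> str:
        return self.module_genes[2]

    @property
    def candidates(self) -> list[str]:
        """The planted candidate plus the decoys, as the screen's gene list."""
        decoys = [
            g
            for g in self.gene_symbols
            if g.startswith("decoy_")
        ][: self.n_decoy_candidates]
        return [self.planted_candidate, *decoys]


def default_sc_spec(
    seed: int = 0,
    n_cells: int = 2000,
    latent_effect: float = 1.5,
    n_module_extras: int = 9,
    n_decoy_candidates: int = 25,
    n_noise_genes: int = 200,
    cell_type_labels: tuple[str, ...] = ("fat_body", "follicle", "muscle"),
    nb_dispersion: float = 2.0,
) -> ScSimSpec:
    """A ready-made single-cell spec emulating a few collagen-producing tissues.

    The planted module is ``Col4a1``, ``vkg``, ``PH4aEFB`` plus
    ``n_module_extras`` co-regulated extras (so the module is large enough to
    survive a minimum-module-size filter); decoy candidate baselines are
    matched to the planted candidate's.  Non-module baselines are drawn
    independently per cell type, giving real cell-type structure; module
    baselines share one per-type activity scalar, reflecting that a
    co-regulated module (collagen subunits drive this: they share a common
    promoter) rises and falls together between tissues.
    """
    module = ["Col4a1", "vkg", "PH4aEFB"] + [
        f"module_extra_{i + 1}" for i in range(n_module_extras)
    ]
    decoys = [f"decoy_{i + 1}" for i in range(n_decoy_candidates)]
    noise = [f"noise_{i + 1}" for i in range(n_noise_genes)]
    genes = module + decoys + noise
    n_genes = len(genes)

    rng = _child_rng(seed, _OFFSET_CELL_TYPES)
    n_types = len(cell_type_labels)

    # one baseline profile for the module, scaled per type by an activity
    module_profile = 10.0 ** rng.uniform(0.0, 1.0, size=len(module))
    cell_types = []
    candidate_idx = 2  # PH4aEFB
    for label in cell_type_labels:
        base = 10.0 ** rng.uniform(-0.5, 1.0, size=n_genes)
        activity = 10.0 ** rng.uniform(-0.3, 0.7)
        base[: len(module)] = module_profile * activity
        # decoys cannot be separable from the planted candidate by level alone
        base[len(module) : len(module) + n_decoy_candidates] = base[candidate_idx]
        cell_types.append(
            CellTypeSpec(label=label, proportion=float(1.0 / n_types), baseline=base)
        )
    # fix rounding of proportions exactly to 1
    cell_types[-1].proportion = 1.0 - sum(ct.proportion for ct in cell_types[:-1])

    return ScSimSpec(
        n_cells=n_cells,
        cell_types=cell_types,
        n_genes=n_genes,
        module_genes=module,
        latent_effect=latent_effect,
        nb_dispersion=nb_dispersion,
        n_decoy_candidates=n_decoy_candidates,
        seed=seed,
        gene_symbols=genes,
    )


def make_cell_counts(spec: ScSimSpec) -> CellCounts:
    """Draw negative-binomial counts with the planted latent-factor module.

    Counts follow the mean-dispersion NB parameterisation (variance
    mu + mu^2/theta), sampled as a gamma-Poisson mixture.  For module genes
    the per-cell mean is ``baseline * exp(latent_effect * z_cell)``.
    Deterministic given ``spec.seed``; the latent factors are drawn from a
    child stream independent of the count stream.
    """
    rng_types = _child_rng(spec.seed, _OFFSET_CELL_TYPES)
    rng_latent = _child_rng(spec.seed, _OFFSET_LATENT)
    rng_counts = _child_rng(spec.seed, _OFFSET_COUNTS)

    proportions = np.array([ct.proportion for ct in spec.cell_types])
    type_idx = rng_types.choice(len(spec.cell_types), size=spec.n_cells, p=proportions)
    z = rng_latent.standard_normal(spec.n_cells)

    module_mask = np.isin(np.array(spec.gene_symbols), np.array(spec.module_genes))
    baselines = np.stack([ct.baseline for ct in spec.cell_types])  # types x genes

    mu = baselines[type_idx]  # cells x genes
    factor = np.exp(spec.latent_effect * z)
    mu = mu.copy()
    mu[:, module_mask] *= factor[:, None]

    theta = spec.nb_dispersion
    lam = np.where(mu > 0, rng_counts.gamma(theta, 1.0, size=mu.shape) * (mu / theta), 0.0)
    counts = rng_counts.poisson(lam)

    cell_ids = [f"cell_{i + 1}" for i in range(spec.n_cells)]
    annotations = pd.Series(
        [spec.cell_types[t].label for t in type_idx], index=cell_ids, dtype=object
    )
    return CellCounts(
        cell_ids=cell_ids,
        gene_symbols=list(spec.gene_symbols),
        counts=sparse.csr_matrix(counts),
        annotations=annotations,
        dataset_id=f"sc_sim_seed{spec.seed}",
    )


def latent_factors(spec: ScSimSpec) -> np.ndarray:
    """The per-cell latent factor z used by :func:`make_cell_counts`.

    Exposed so tests can compare recovered module eigengenes against the
    generating factor.
    """
    return _child_rng(spec.seed, _OFFSET_LATENT).standard_normal(spec.n_cells)


@dataclass
class AssignmentFixture:
    """Per-group module assignments with known candidate co-assignment count."""

    networks: list[pd.Series]  # gene -> module label, one per group
    substrate_pair: tuple[str, str]
    candidates: list[str]

    def __post_init__(self) -> None:
        for i, assignment in enumerate(self.networks):
            for gene in self.substrate_pair:
                if gene not in assignment.index:
                    raise SpecificationError(
                        f"network {i}: substrate gene {gene!r} missing"
                    )

    def assignments(self) -> dict[str, pd.Series]:
        return {f"group_{i + 1}": a for i, a in enumerate(self.networks)}


def make_assignment_fixture(
    n_networks: int,
    module_sizes: list[list[int]],
    planted_matches: int,
    seed: int = 0,
    n_candidates: int = 3,
) -> AssignmentFixture:
    """Build per-network assignments with exactly ``planted_matches`` matches.

    In ``planted_matches`` networks the substrate pair and the first candidate
    share a module; in the remaining networks the pair still shares a module
    but the candidate sits elsewhere.  ``module_sizes[i]`` lists the module
    sizes of network i; their sum is the network's gene count and must leave
    room for the pair and the candidate.
    """
    if planted_matches > n_networks:
        raise SpecificationError("planted_matches cannot exceed n_networks")
    if len(module_sizes) != n_networks:
        raise SpecificationError("module_sizes must list one profile per network")

    rng = _child_rng(seed, _OFFSET_FIXTURE)
    pair = ("Col4a1", "vkg")
    candidates = ["PH4aEFB"] + [f"decoy_{i + 1}" for i in range(n_candidates - 1)]

    networks = []
    for i, sizes in enumerate(module_sizes):
        n_genes = int(sum(sizes))
        if len(sizes) < 2 and planted_matches < n_networks:
            raise SpecificationError(
                f"network {i}: need >= 2 modules to place the candidate elsewhere"
            )
        if n_genes < 2 + len(candidates):
            raise SpecificationError(
                f"network {i}: {n_genes} genes cannot hold the pair and "
                f"{len(candidates)} candidates"
            )
        if min(sizes) < 1:
            raise SpecificationError(f"network {i}: every module needs >= 1 member")
        fillers = [f"g{i}_{j}" for j in range(n_genes - 2 - len(candidates))]
        genes = list(pair) + candidates + fillers

        labels = np.concatenate(
            [np.full(s, f"M{m + 1}", dtype=object) for m, s in enumerate(sizes)]
        )
        # place pair together in the largest module; candidate per planted flag
        order = np.argsort([-s for s in sizes], kind="stable")
        pair_module = f"M{order[0] + 1}"
        slots = {label: list(np.where(labels == label)[0]) for label in set(labels)}
        assignment = np.empty(n_genes, dtype=object)

        def take(module_label: str) -> int:
            return slots[module_label].pop(0)

        placed: dict[str, str] = {}
        placed[pair[0]] = pair_module
        placed[pair[1]] = pair_module
        take(pair_module), take(pair_module)
        if i < planted_matches:
            if not slots[pair_module]:
                raise SpecificationError(
                    f"network {i}: substrate module too small to also hold the candidate"
                )
            placed[candidates[0]] = pair_module
            take(pair_module)
        else:
            other = [m for m in slots if m != pair_module and slots[m]]
            if not other:
                raise SpecificationError(
                    f"network {i}: no second module to hold the candidate"
                )
            m = other[0]
            placed[candidates[0]] = m
            take(m)
        remaining_genes = [g for g in genes if g not in placed]
        remaining_slots = [m for m, idxs in slots.items() for _ in idxs]
        rng.shuffle(remaining_slots)
        for g, m in zip(remaining_genes, remaining_slots):
            placed[g] = m
        networks.append(pd.Series({g: placed[g] for g in genes}, dtype=object))

    return AssignmentFixture(
        networks=networks, substrate_pair=pair, candidates=candidates
    )
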