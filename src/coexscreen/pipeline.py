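"""End-to-end pipeline runner and its run configuration.

A run executes six stages in order — simulate, metacell, modules, cooccur,
quadrants, screen — writing each stage's artifacts into the run directory
and a ``manifest.json`` recording parameter values, child seeds, row/column
counts and sha256 checksums of every artifact.  All randomness flows from
the single config seed through fixed-offset child seeds, so a rerun with the
same config reproduces every artifact byte-for-byte (timestamps live only in
the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cxio
from .cooccurrence import permutation_test
from .errors import CoexscreenError, SpecificationError
from .network import NetworkParams, fit_group_networks
from .preprocess import MetacellParams, PreprocessParams, run_preprocessing
from .screen import correlation_screen, quadrant_classify
from .simulate import BulkSimSpec, default_sc_spec, make_bulk_table, make_cell_counts

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# fixed offsets expanding the run seed into per-stage child seeds
_SEED_OFFSETS = {"simulate_bulk": 11, "simulate_sc": 12, "metacell": 13, "cooccur": 14}
_MOD = 2**31


def _child_seed(seed: int, stage: str) -> int:
    return (int(seed) * 100 + _SEED_OFFSETS[stage]) % _MOD


@dataclass
class SimulateBlock:
    """Synthetic-data settings for a run that generates its own inputs."""

    enabled: bool = True
    bulk_n_genes: int = 28
    bulk_n_samples: int = 25
    bulk_target_correlation: float = 0.8
    sc_n_cells: int = 2000
    sc_latent_effect: float = 1.5


@dataclass
class CooccurBlock:
    n_permutations: int = 10_000
    null_mode: str = "shuffle_all"


@dataclass
class QuadrantBlock:
    gene_x: str = "Col4a1"
    gene_y: str = "PH4aEFB"
    hi: float = 1.0
    lo: float = 0.1


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Every stage block validates on construction, before any stage executes;
    the config round-trips losslessly through its YAML form.
    """

    out_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    # the synthetic panel has a few hundred genes, so the detected-gene QC
    # floor is scaled down from the real-data default of 200
    preprocess: PreprocessParams = field(
        default_factory=lambda: PreprocessParams(min_genes_per_cell=10)
    )
    metacell: MetacellParams = field(default_factory=MetacellParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    cooccur: CooccurBlock = field(default_factory=CooccurBlock)
    quadrants: QuadrantBlock = field(default_factory=QuadrantBlock)
    counts_mtx: str | None = None
    counts_genes: str | None = None
    counts_annotations: str | None = None
    bulk_table: str | None = None

    def __post_init__(self) -> None:
        if not self.simulate.enabled:
            missing = [
                name
                for name, value in [
                    ("counts_mtx", self.counts_mtx),
                    ("counts_genes", self.counts_genes),
                    ("counts_annotations", self.counts_annotations),
                    ("bulk_table", self.bulk_table),
                ]
                if value is None
            ]
            if missing:
                raise SpecificationError(
                    "simulation disabled but input paths missing: "
                    + ", ".join(missing)
                )
        if self.cooccur.n_permutations < 1:
            raise SpecificationError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        blocks = {
            "simulate": SimulateBlock,
            "preprocess": PreprocessParams,
            "metacell": MetacellParams,
            "network": NetworkParams,
            "cooccur": CooccurBlock,
            "quadrants": QuadrantBlock,
        }
        kwargs = {}
        for key, value in data.items():
            if key in blocks and isinstance(value, dict):
                kwargs[key] = blocks[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage failures halt the run with a stage-named error; artifacts written
    so far are left in place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log_file = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(log_file)

    manifest: dict = {
        "seed": config.seed,
        "child_seeds": {k: _child_seed(config.seed, k) for k in _SEED_OFFSETS},
        "config": config.to_dict(),
        "stages": [],
        "artifacts": {},
    }

    def record(stage: str, paths: dict[str, Path], started: float, **extra) -> None:
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.time() - started, 3), **extra}
        )
        for name, path in paths.items():
            manifest["artifacts"][name] = {
                "path": str(path.relative_to(out)),
                "sha256": _sha256(path),
                "bytes": path.stat().st_size,
            }

    state: dict = {}
    try:
        # ---- stage 1: simulate (or load) inputs -------------------------
        started = time.time()
        if config.simulate.enabled:
            bulk_spec = BulkSimSpec(
                n_genes=config.simulate.bulk_n_genes,
                n_samples=config.simulate.bulk_n_samples,
                target_correlation=config.simulate.bulk_target_correlation,
                seed=_child_seed(config.seed, "simulate_bulk"),
            )
            bulk = make_bulk_table(bulk_spec)
            sc_spec = default_sc_spec(
                seed=_child_seed(config.seed, "simulate_sc"),
                n_cells=config.simulate.sc_n_cells,
                latent_effect=config.simulate.sc_latent_effect,
            )
            counts = make_cell_counts(sc_spec)
            state["candidates"] = sc_spec.candidates
            state["substrate_pair"] = sc_spec.substrate_pair
            state["focal_candidate"] = sc_spec.planted_candidate
            paths = {
                "bulk_table": cxio.write_expression_tsv(bulk, out / "bulk_table.tsv"),
            }
            cxio.write_counts_mtx(
                counts,
                out / "counts.mtx",
                out / "counts_genes.tsv",
                out / "counts_cells.tsv",
            )
            paths["counts_mtx"] = out / "counts.mtx"
            paths["counts_genes"] = out / "counts_genes.tsv"
            paths["counts_cells"] = out / "counts_cells.tsv"
            record("simulate", paths, started, n_cells=counts.n_cells,
                   n_bulk_genes=bulk.n_genes)
        else:
            bulk = cxio.read_expression_tsv(config.bulk_table)
            counts = cxio.read_counts_mtx(
                config.counts_mtx, config.counts_genes, config.counts_annotations
            )
            state["substrate_pair"] = ("Col4a1", "vkg")
            state["candidates"] = [
                g for g in counts.gene_symbols if g not in state["substrate_pair"]
            ]
            state["focal_candidate"] = "PH4aEFB"
            record("simulate", {}, started, loaded=True, n_cells=counts.n_cells)
        state["bulk"], state["counts"] = bulk, counts

        # ---- stage 2: metacell ------------------------------------------
        started = time.time()
        mparams = dataclasses.replace(
            config.metacell, seed=_child_seed(config.seed, "metacell")
        )
        metacells = run_preprocessing(counts, config.preprocess, mparams)
        paths = {
            "metacells": cxio.write_metacell_tsv(
                metacells, out / "metacells.tsv", out / "metacell_members.tsv"
            ),
            "metacell_members": out / "metacell_members.tsv",
        }
        record("metacell", paths, started, n_metacells=metacells.n_metacells)
        state["metacells"] = metacells

        # ---- stage 3: modules -------------------------------------------
        started = time.time()
        networks = fit_group_networks(metacells, config.network)
        if not networks:
            raise CoexscreenError("modules stage produced no networks")
        paths = {}
        net_dir = out / "networks"
        for group, result in networks.items():
            assign = result.assignment.rename("module").to_frame()
            assign.index.name = "gene"
            p = net_dir / f"{group}_assignment.tsv"
            p.parent.mkdir(parents=True, exist_ok=True)
            assign.to_csv(p, sep="\t")
            paths[f"assignment_{group}"] = p
            e = net_dir / f"{group}_eigengenes.tsv"
            result.eigengenes.to_csv(e, sep="\t", index=False)
            paths[f"eigengenes_{group}"] = e
            km = net_dir / f"{group}_kme.tsv"
            result.kme.to_csv(km, sep="\t")
            paths[f"kme_{group}"] = km
            ft = net_dir / f"{group}_fit.tsv"
            result.fit_table.to_csv(ft, sep="\t", index=False)
            paths[f"fit_{group}"] = ft
        record("modules", paths, started, groups=sorted(networks))
        state["networks"] = networks

        # ---- stage 4: cooccur -------------------------------------------
        started = time.time()
        assignments = {g: r.assignment for g, r in networks.items()}
        result = permutation_test(
            assignments,
            state["substrate_pair"],
            state["candidates"],
            state["focal_candidate"],
            n_permutations=config.cooccur.n_permutations,
            seed=_child_seed(config.seed, "cooccur"),
            null_mode=config.cooccur.null_mode,
        )
        p = out / "cooccurrence.tsv"
        result.to_frame().to_csv(p, sep="\t", index=False)
        record("cooccur", {"cooccurrence": p}, started,
               p_report=result.p_report, matches=result.empirical_matches)
        state["cooccurrence"] = result

        # ---- stage 5: quadrants -----------------------------------------
        started = time.time()
        q = quadrant_classify(
            metacells,
            config.quadrants.gene_x,
            config.quadrants.gene_y,
            hi=config.quadrants.hi,
            lo=config.quadrants.lo,
        )
        rows = [
            {"quadrant": name, "count": q.counts[name]} for name in q.QUADRANTS
        ]
        p = out / "quadrants.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        record("quadrants", {"quadrants": p}, started)
        state["quadrants"] = q

        # ---- stage 6: screen --------------------------------------------
        started = time.time()
        candidates = [g for g in bulk.gene_symbols if g != bulk.gene_symbols[0]]
        screen = correlation_screen(bulk, bulk.gene_symbols[0], candidates)
        p = out / "screen_ranked.tsv"
        screen.records.to_csv(p, sep="\t", index=False)
        record("screen", {"screen_ranked": p}, started,
               top_gene=screen.records["gene"].iloc[0])
        state["screen"] = screen
    except CoexscreenError as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise CoexscreenError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logging.getLogger().removeHandler(log_file)
        log_file.close()
    return out
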