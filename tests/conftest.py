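import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import coexscreen as cx
from coexscreen.simulate import latent_factors

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_table():
    """Tiny 3-gene, 4-sample table with hand-checkable values."""
    return cx.ExpressionTable(
        gene_symbols=["Col4a1", "vkg", "flat"],
        sample_labels=["s1", "s2", "s3", "s4"],
        values=np.array([[0.0, 2.0, 4.0, 1.0], [1.0, 3.0, 5.0, 2.0], [2.0, 2.0, 2.0, 2.0]]),
        dataset_id="tiny",
    )


@pytest.fixture
def small_metacells():
    """Six metacells in two groups, three genes, hand-set values."""
    ids = [f"mc{i}" for i in range(1, 7)]
    expr = np.array(
        [
            # Col4a1, PH4aEFB, other
            [2.0, 0.05, 1.0],
            [1.5, 0.00, 0.2],
            [0.5, 2.00, 0.1],
            [0.2, 1.50, 0.4],
            [2.5, 3.00, 0.3],
            [0.5, 0.05, 0.9],
        ]
    )
    groups = pd.Series(
        ["fat_body", "fat_body", "unannotated", "unannotated", "fat_body", "ovary"],
        index=ids,
    )
    return cx.MetacellMatrix(
        metacell_ids=ids,
        gene_symbols=["Col4a1", "PH4aEFB", "other"],
        expression=expr,
        group_labels=groups,
        dataset_id="toy",
    )


@pytest.fixture(scope="session")
def sc_bundle():
    """One full synthetic single-cell run shared across the suite.

    Returns the spec, raw counts, per-cell latent factors, the metacell
    matrix, and the per-group fitted networks under default study
    conditions (2000 cells, latent effect 1.5, k=25, max_shared=10).
    """
    spec = cx.default_sc_spec(seed=11, n_cells=2000, latent_effect=1.5)
    counts = cx.make_cell_counts(spec)
    pparams = cx.PreprocessParams(min_genes_per_cell=10)
    mparams = cx.MetacellParams(seed=7)
    metacells = cx.run_preprocessing(counts, pparams, mparams)
    networks = cx.fit_group_networks(metacells, cx.NetworkParams())
    return {
        "spec": spec,
        "counts": counts,
        "latent": dict(zip(counts.cell_ids, latent_factors(spec))),
        "metacells": metacells,
        "mparams": mparams,
        "networks": networks,
    }
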