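"""Co-expression network construction: power selection, TOM, modules, kME."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import coexscreen as cx
from coexscreen.network import (
    adjacency,
    correlation_matrix,
    detect_modules,
    fit_connectivity_distribution,
    kme,
    module_eigengene,
    scale_free_fit,
    select_soft_power,
    topological_overlap,
)


def _two_block_expr(rng, n_per_block=20, n_samples=100, noise=0.4):
    """Two planted modules driven by independent latent factors."""
    f1 = rng.normal(size=n_samples)
    f2 = rng.normal(size=n_samples)
    block1 = f1[:, None] + noise * rng.normal(size=(n_samples, n_per_block))
    block2 = f2[:, None] + noise * rng.normal(size=(n_samples, n_per_block))
    return np.hstack([block1, block2])


def _graded_factor_expr(rng, n_samples=120, n_genes=60, noise=0.8):
    """One latent factor with graded gene loadings: a broad connectivity
    spectrum whose weighted network is close to scale-free."""
    f = rng.normal(size=n_samples)
    loadings = rng.uniform(0, 1, size=n_genes) ** 2
    return f[:, None] * loadings[None, :] + noise * rng.normal(
        size=(n_samples, n_genes)
    )


class TestScaleFreeFit:
    def test_exact_power_law_scores_one(self):
        # connectivity frequencies following exactly freq = C * k^-2: the
        # binned log-log regression is perfectly linear with negative slope
        levels = np.arange(1, 7, dtype=float)
        counts = (3600 / levels**2).astype(int)  # 3600/k^2 is integral here
        k = np.repeat(levels, counts)
        assert fit_connectivity_distribution(k) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_binned_regression(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(50, 30))
        r2, mean_k = scale_free_fit(expr, power=6)
        # independent oracle: recompute the binned regression from scratch
        k = adjacency(expr, 6).sum(axis=1)
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            sel = idx == b
            if sel.any() and k[sel].mean() > 0:
                xs.append(np.log10(k[sel].mean()))
                ys.append(np.log10(sel.sum() / k.size))
        fit = stats.linregress(xs, ys)
        assert r2 == pytest.approx(-np.sign(fit.slope) * fit.rvalue**2)
        assert mean_k == pytest.approx(k.mean())

    def test_degenerate_identical_genes_reported_missing(self):
        base = np.random.default_rng(1).normal(size=50)
        expr = np.tile(base[:, None], (1, 10))
        r2, _ = scale_free_fit(expr, power=6)
        assert math.isnan(r2)


class TestSoftPowerSelection:
    def test_lowest_qualifying_power_selected(self):
        rng = np.random.default_rng(2)
        expr = _graded_factor_expr(rng)
        params = cx.NetworkParams()
        beta, table, warning = select_soft_power(expr, params)
        qualifying = table.dropna(subset=["signed_r2"])
        qualifying = qualifying[qualifying["signed_r2"] >= params.fit_threshold]
        assert not warning
        assert beta == int(qualifying["power"].min())

    def test_zero_threshold_returns_smallest_power(self):
        rng = np.random.default_rng(3)
        expr = _two_block_expr(rng)
        params = cx.NetworkParams(fit_threshold=1e-9)
        beta, table, warning = select_soft_power(expr, params)
        first_defined = table.dropna(subset=["signed_r2"])
        positive = first_defined[first_defined["signed_r2"] >= 1e-9]
        assert beta == int(positive["power"].min())

    def test_fallback_to_argmax_with_warning(self):
        rng = np.random.default_rng(4)
        expr = _two_block_expr(rng)
        params = cx.NetworkParams(fit_threshold=0.999999)
        beta, table, warning = select_soft_power(expr, params)
        assert warning
        defined = table.dropna(subset=["signed_r2"])
        assert beta == int(defined.loc[defined["signed_r2"].idxmax(), "power"])


class TestAdjacency:
    def test_perfect_correlation_maps_to_one(self):
        x = np.arange(10.0)
        expr = np.column_stack([x, 2 * x + 1])
        adj = adjacency(expr, beta=7, signed=True)
        assert adj[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation_maps_to_zero_signed(self):
        x = np.arange(10.0)
        expr = np.column_stack([x, -x])
        adj = adjacency(expr, beta=3, signed=True)
        assert adj[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independence_at_beta_six(self):
        # orthogonal, zero-correlation pair: ((1+0)/2)^6 = 0.015625
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        adj = adjacency(np.column_stack([x, y]), beta=6, signed=True)
        assert adj[0, 1] == pytest.approx(0.5**6)

    def test_monotone_decreasing_in_beta(self):
        rng = np.random.default_rng(5)
        expr = rng.normal(size=(30, 12))
        a_low = adjacency(expr, beta=2)
        a_high = adjacency(expr, beta=9)
        off = ~np.eye(12, dtype=bool)
        assert np.all(a_high[off] <= a_low[off] + 1e-12)

    def test_zero_variance_gene_rejected(self):
        expr = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(cx.DomainError):
            correlation_matrix(expr)


class TestTopologicalOverlap:
    def test_hand_evaluated_three_gene_case(self):
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 0.0)
        tom = topological_overlap(adj)
        # (0.25 + 0.5) / (min(1,1) + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    def test_zero_adjacency_gives_zero_overlap(self):
        tom = topological_overlap(np.zeros((4, 4)))
        off = ~np.eye(4, dtype=bool)
        assert np.all(tom[off] == 0)
        assert np.all(np.diag(tom) == 1)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(6)
        adj = rng.uniform(0, 1, size=(6, 6))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        tom = topological_overlap(adj)
        n = 6
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(
                    adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j)
                )
                ki = sum(adj[i, u] for u in range(n) if u != i)
                kj = sum(adj[j, u] for u in range(n) if u != j)
                expected = (shared + adj[i, j]) / (min(ki, kj) + 1 - adj[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-10)

    def test_asymmetric_input_rejected(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = 0.5
        with pytest.raises(cx.DomainError):
            topological_overlap(adj)

    @given(arrays(float, (7, 7), elements=st.floats(0, 1)))
    def test_range_symmetry_and_diagonal_properties(self, raw):
        adj = (raw + raw.T) / 2
        np.fill_diagonal(adj, 0.0)
        tom = topological_overlap(adj)
        assert np.all(tom >= 0) and np.all(tom <= 1)
        assert np.allclose(tom, tom.T)
        assert np.all(np.diag(tom) == 1)


class TestModuleDetection:
    def test_two_planted_blocks_recovered_across_seeds(self):
        truth = np.array([0] * 20 + [1] * 20)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            expr = _two_block_expr(rng)
            tom = topological_overlap(adjacency(expr, beta=6))
            genes = [f"g{i}" for i in range(40)]
            assignment = detect_modules(tom, genes, cx.NetworkParams())
            labels = pd.factorize(assignment)[0]
            assert adjusted_rand_score(truth, labels) >= 0.9

    def test_identical_genes_form_a_single_module(self):
        base = np.random.default_rng(7).normal(size=30)
        expr = np.tile(base[:, None], (1, 12))
        adj = np.ones((12, 12))
        np.fill_diagonal(adj, 0.0)
        tom = topological_overlap(adj)
        assignment = detect_modules(tom, [f"g{i}" for i in range(12)], cx.NetworkParams())
        assert set(assignment) == {"M1"}

    def test_pure_noise_left_unassigned_at_strong_min_size(self):
        rng = np.random.default_rng(8)
        expr = rng.normal(size=(120, 30))
        tom = topological_overlap(adjacency(expr, beta=6))
        params = cx.NetworkParams(min_module_size=15)
        assignment = detect_modules(tom, [f"g{i}" for i in range(30)], params)
        assert set(assignment) == {"unassigned"}

    def test_fewer_genes_than_min_size_all_unassigned(self):
        tom = np.eye(4)
        assignment = detect_modules(
            tom, list("abcd"), cx.NetworkParams(min_module_size=10)
        )
        assert set(assignment) == {"unassigned"}


class TestEigengeneAndKme:
    def test_single_gene_module_has_unit_kme(self):
        rng = np.random.default_rng(9)
        expr = rng.normal(size=(50, 1)) + 3
        assignment = pd.Series({"g0": "M1"})
        eig = module_eigengene(expr, ["g0"], assignment)
        z = (expr[:, 0] - expr[:, 0].mean()) / expr[:, 0].std()
        assert np.allclose(np.abs(eig["M1"]), np.abs(z / np.linalg.norm(z)), atol=1e-9)
        km = kme(expr, ["g0"], eig)
        assert km.loc["g0", "M1"] == pytest.approx(1.0)

    def test_identical_member_genes_correlate_one_with_eigengene(self):
        base = np.random.default_rng(10).normal(size=40)
        expr = np.tile(base[:, None], (1, 5))
        genes = [f"g{i}" for i in range(5)]
        assignment = pd.Series("M1", index=genes)
        eig = module_eigengene(expr, genes, assignment)
        km = kme(expr, genes, eig)
        assert np.allclose(km["M1"], 1.0)

    def test_eigengene_is_variance_maximal_unit_combination(self):
        rng = np.random.default_rng(11)
        expr = _two_block_expr(rng, n_per_block=6)
        genes = [f"g{i}" for i in range(12)]
        assignment = pd.Series(["M1"] * 6 + ["M2"] * 6, index=genes)
        eig = module_eigengene(expr, genes, assignment)
        sub = expr[:, :6]
        z = (sub - sub.mean(0)) / sub.std(0)
        # the eigengene is the score vector of the leading right singular
        # direction: no other unit-norm gene combination has larger variance
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        best = z @ vt[0]
        assert abs(np.corrcoef(eig["M1"], best)[0, 1]) > 1 - 1e-9
        for _ in range(200):
            w = rng.normal(size=6)
            w /= np.linalg.norm(w)
            assert np.var(z @ w) <= np.var(best) + 1e-9

    def test_independent_gene_has_small_kme(self):
        rng = np.random.default_rng(12)
        n = 300
        factor = rng.normal(size=n)
        members = factor[:, None] + 0.3 * rng.normal(size=(n, 8))
        outsider = rng.normal(size=(n, 1))
        expr = np.hstack([members, outsider])
        genes = [f"g{i}" for i in range(9)]
        assignment = pd.Series(["M1"] * 8 + ["unassigned"], index=genes)
        eig = module_eigengene(expr, genes, assignment)
        km = kme(expr, genes, eig)
        assert abs(km.loc["g8", "M1"]) < 0.3

    def test_kme_matches_direct_correlation_loop(self):
        rng = np.random.default_rng(13)
        expr = _two_block_expr(rng, n_per_block=5, n_samples=60)
        genes = [f"g{i}" for i in range(10)]
        assignment = pd.Series(["M1"] * 5 + ["M2"] * 5, index=genes)
        eig = module_eigengene(expr, genes, assignment)
        km = kme(expr, genes, eig)
        for g_idx, gene in enumerate(genes):
            for module in eig.columns:
                expected = np.corrcoef(expr[:, g_idx], eig[module])[0, 1]
                assert km.loc[gene, module] == pytest.approx(expected, abs=1e-12)


class TestCoexpressionNetworkModel:
    def test_fit_recovers_planted_module_and_reports(self, sc_bundle):
        networks = sc_bundle["networks"]
        spec = sc_bundle["spec"]
        assert networks  # one per simulated cell type with enough metacells
        for group, result in networks.items():
            pair_module = result.module_of("Col4a1")
            assert pair_module != "unassigned"
            assert result.module_of("vkg") == pair_module
            assert result.module_of(spec.planted_candidate) == pair_module
            assert group in result.summary()
            # eigengenes unit-norm; kME within [-1, 1]
            for m in result.modules():
                assert np.linalg.norm(result.eigengenes[m]) == pytest.approx(1.0)
            finite = result.kme.to_numpy()[np.isfinite(result.kme.to_numpy())]
            assert np.all(finite <= 1.0 + 1e-12) and np.all(finite >= -1.0 - 1e-12)

    def test_eigengene_tracks_generating_latent_factor(self, sc_bundle):
        metacells = sc_bundle["metacells"]
        latent = sc_bundle["latent"]
        for group, result in sc_bundle["networks"].items():
            module = result.module_of("Col4a1")
            sub = metacells.subset_group(group)
            eig = result.eigengenes[module].to_numpy()
            zbar = np.array(
                [
                    np.mean([latent[c] for c in sub.membership[mc]])
                    for mc in sub.metacell_ids
                ]
            )
            assert abs(np.corrcoef(eig, zbar)[0, 1]) > 0.9

    def test_too_few_varying_genes_rejected(self):
        frame = pd.DataFrame(np.random.default_rng(14).normal(size=(20, 5)))
        with pytest.raises(cx.SpecificationError):
            cx.CoexpressionNetwork(frame, "g").fit()
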