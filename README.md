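# coexscreen

Co-expression screening for enzyme/substrate gene pairs across bulk and
single-cell transcriptomes.

Intracellular enzymes must be expressed in the same cells as their
substrates. When a genome carries many candidate genes for one enzymatic
activity — the motivating case is *Drosophila melanogaster*, whose genome
annotates ~26 prolyl-4-hydroxylase-α-related genes against a single major
substrate, collagen IV (subunits *Col4a1* and *viking*) — co-expression
becomes a powerful filter: the candidate that tracks the substrate across
tissues, perturbations, developmental time, and single cells is the likely
enzyme. `coexscreen` implements that screen end to end:

1. **Reference-gene correlation screen** — Pearson
   *r* = cov(x, y) / (σₓ σᵧ) of every candidate against the reference gene
   over a wide expression compendium, ranked descending, with per-gene
   max-normalisation for display and peak-time ordering for time courses.
2. **Metacell aggregation** — single-cell QC, counts-per-10k ln(1+x)
   normalisation, variable-gene selection, PCA, and per-cell-type KNN
   metacells (k = 25 members, pairwise overlap ≤ 10) to beat single-cell
   sparsity.
3. **Weighted co-expression networks** per cell type — signed adjacency
   a(i,j) = ((1 + cor)/2)^β with β chosen as the lowest power reaching a
   0.8 scale-free topology fit, topological overlap (TOM), average-linkage
   modules, module eigengenes, and eigengene connectivity (kME).
4. **Module co-occurrence test** — a Monte Carlo permutation test of how
   often a candidate shares a module with the substrate pair across
   cell-type networks, `p = #(matches ≥ observed) / N` with "< 1/N"
   reporting, plus an exact convolution oracle.
5. **Quadrant classification** — strict-threshold selections of metacells
   (e.g. substrate > 1 and candidate < 0.1) with per-annotation breakdowns.
6. **Synthetic data** — seeded negative-binomial single-cell counts and
   lognormal bulk compendia with planted ground truth for every stage.

## Worked example

Screen 27 candidates against a reference gene on a synthetic 25-sample
compendium with a planted partner (target r = 0.8), then test module
co-occurrence on a three-network fixture:

```python
import coexscreen as cx

table = cx.make_bulk_table(cx.BulkSimSpec(n_samples=25, target_correlation=0.8, seed=1))
candidates = [g for g in table.gene_symbols if g != "Col4a1"]
result = cx.CorrelationScreen(table, "Col4a1", candidates).fit()
print(result.records.head(5).to_string(index=False))

fixture = cx.make_assignment_fixture(
    n_networks=3, module_sizes=[[12, 8], [10, 10], [15, 5]], planted_matches=3, seed=0
)
test = cx.ModuleCooccurrenceTest(
    fixture.assignments(), fixture.substrate_pair, fixture.candidates, "PH4aEFB"
)
print(test.fit(n_permutations=10_000, seed=1).summary())
```

```
   gene        r  n  rank
PH4aEFB 0.821983 25     1
    CG4 0.511252 25     2
   CG12 0.314146 25     3
   CG15 0.273150 25     4
   CG18 0.272063 25     5

Module co-occurrence permutation test
  candidate: PH4aEFB
  networks (cell types) with candidate/substrate co-expression: 3
  networks (cell types) with substrate-pair co-expression: 3
  p =0.0198  (10000 replicates, null mode shuffle_all, seed 1)
```

The planted partner tops the ranking with sample r ≈ 0.82 against the 0.8
target; sharing a module with the substrate pair in all three cell-type
networks is unlikely under label permutation (p ≈ 0.02).

A command-line interface mirrors the library
(`coexscreen simulate|screen|metacell|modules|cooccur|quadrants|run`); the
`run` subcommand executes the whole pipeline from a YAML config and writes
a manifest with parameters, child seeds and artifact checksums. See
`docs/methods.md` for the statistical details and design choices.

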