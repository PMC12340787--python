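# Methods

`coexscreen` implements the transcriptomic machinery for asking which of a
pool of candidate enzyme genes is co-regulated with a substrate gene pair —
the motivating case being the *Drosophila* collagen IV subunits *Col4a1* and
*viking* (*vkg*) and the ~26 prolyl-4-hydroxylase-α-related candidate genes.
This note describes the statistical procedures, the defaults and why they
were chosen, what the synthetic data emulate (and do not), and the numerical
conventions.

## 1. Reference-gene correlation screen (bulk compendia)

For a wide genes × samples table, each candidate gene is scored by the
Pearson correlation *r* of its expression vector with the reference gene's,
over all samples, and candidates are ranked by *r* descending (ties broken
by input order). Correlations are computed on raw values: Pearson *r* is
invariant to positive per-gene affine rescaling, so the per-gene
max-normalisation used for display (each row divided by its maximum;
all-zero rows left at zero) never enters the statistic. An *r* that is
undefined because either vector has zero variance is reported as missing,
never coerced to 0 — all-zero genes do occur in real compendia. When
comparing against values printed to two decimals, rounding is half-up
(`round_half_up`).

Peak-time ordering for developmental time courses sorts genes by the sample
index of the first attainment of their maximum (plateaus resolve to the
first sample; all-zero genes go last).

## 2. Single-cell preprocessing and metacells

Cells are kept when their detected-gene count lies within
`[min_genes_per_cell, max_genes_per_cell]` inclusive (defaults 200 and
2500; the customary per-tissue ceiling spans roughly 2000–3500 and differs
between tissues, so the midpoint is the default and the bound is an
ordinary knob). Genes detected in fewer than `ceil(0.05 × n_cells)` cells
are dropped. Counts are normalised per cell to a fixed total
(`scale_factor` = 10,000, i.e. counts-per-10k) and transformed with
ln(1 + x); natural log is the convention of the standard single-cell
toolchains. The 2000 most variable genes are chosen by binned standardized
dispersion: genes are placed into 20 equal-frequency bins of mean
expression and the classic dispersion (variance/mean of the expm1 scale) is
z-scored within each bin; strictly constant genes are never selected, and
ties resolve by gene input order. Cells are embedded by PCA on per-gene
z-scores clipped at ±10, keeping 50 components (or fewer if the panel is
smaller); each component is oriented so its largest-magnitude gene loading
is positive, making the embedding reproducible across linear-algebra
backends.

Metacells are built per annotation group with k = 25 member cells and at
most `max_shared` = 10 members shared between any two metacells. Seed cells
are drawn without replacement in a seeded random order (cycling through the
group); each candidate metacell is the seed plus its k−1 nearest
within-group neighbours in the embedding (Euclidean; neighbour ties resolve
by cell input order); a candidate is accepted iff its overlap with every
accepted metacell is within the cap. A group stops after
`max_attempts_per_group` (default 5000) consecutive rejections — or after a
full cycle of rejections, since rejection is deterministic given the
accepted set. Groups smaller than k are skipped with a log line, not an
error.

Metacell expression is the per-gene mean of the members' log-normalised
expression. Because a mean of log values is no longer on a fixed
counts-per-10k scale, the default re-normalisation maps the mean back to
the linear scale with expm1, rescales the metacell to `scale_factor` total,
and re-logs with log1p. This choice is switchable
(`MetacellParams.renormalize`) because the appropriate metacell-matrix
normalisation is genuinely open; the pipeline logs which was used.

## 3. Weighted co-expression networks per cell type

Within each group's metacell matrix (zero-variance genes removed with a log
line; they remain in the gene universe as "unassigned"):

* **Adjacency.** Signed soft-thresholding
  `a_ij = ((1 + cor_ij)/2)^β` (unsigned `|cor_ij|^β` available); Pearson
  correlations throughout. Perfect anticorrelation maps to 0, independence
  to `0.5^β`.
* **Soft power.** β is the smallest integer in 1..30 whose network passes a
  scale-free topology fit of 0.8: connectivities `k_i = Σ_{j≠i} a_ij` are
  binned into 10 equal-width bins (empty or zero-mean bins dropped),
  log10(frequency) is regressed on log10(mean k), and the statistic is
  `−sign(slope) · R²` so a decaying connectivity law scores positively.
  Fewer than three usable bins leaves the fit undefined; if no power
  qualifies the argmax power is used and flagged with a warning.
* **Topological overlap.**
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with zero
  diagonal in `a` (so the shared-neighbour sum excludes i and j) and
  `TOM_ii = 1`; symmetric with entries in [0, 1].
* **Modules.** Average-linkage hierarchical clustering on 1 − TOM with a
  *static* cut at `cut_height_fraction` (default 0.99) of the maximum merge
  height; clusters below `min_module_size` (default 10) are relabelled
  "unassigned", and surviving modules are named M1, M2, … by decreasing
  size. A static cut is used instead of dynamic tree cutting because it is
  fully specifiable, deterministic, and testable; `CoexpressionNetwork`
  accepts a custom `module_detector` for anyone who wants a different
  cutter, and the static cut is not claimed to be equivalent to dynamic
  variants.
* **Eigengenes and kME.** A module eigengene is the first principal
  component score vector (unit norm over metacells) of the z-scored member
  submatrix, oriented so its mean correlation with members is nonnegative;
  kME is the Pearson correlation of every gene with every eigengene.

## 4. Module co-occurrence permutation test

A network is *eligible* when both substrate genes carry the same
non-"unassigned" module label. The empirical statistic is the number of
eligible networks in which the focal candidate shares that module. The
Monte Carlo null permutes each network's gene→module assignment vector
(preserving the module-size multiset), draws one candidate uniformly from
the candidate pool in every replicate, and recomputes eligibility and
matches; with N replicates the p-value is the plain proportion of
replicates whose match count reaches the empirical value. The plain
proportion (no +1 correction) is used so that zero exceedances report as
"< 1/N" — e.g. "< 0.0001" at N = 10,000.

Two null modes are provided because "randomise the assignments" admits two
readings: `shuffle_all` (default) randomises everything, including
eligibility; `random_candidate_slot` holds eligibility at its observed
value and drops the candidate into a uniformly random gene slot of each
eligible network. "Unassigned" genes never count as co-assigned but are
permuted like any other label. The reported "number of networks" counts
cell-type networks, one per annotation group, not distinct modules.

An exact oracle computes the same tail analytically: per network the match
event is Bernoulli with probability `Σ_m s_m(s_m−1)(s_m−2) / (n(n−1)(n−2))`
over real modules (shuffle-all; an ordered triple of distinct slots in one
module) or `s_substrate/n` (candidate-slot), and the distribution of the
sum of independent Bernoullis is built by brute-force convolution. The test
suite requires the Monte Carlo p to sit within three Monte Carlo standard
errors of this oracle on small fixtures in both modes.

## 5. Synthetic data: what it emulates, and what it does not

The generators provide seeded ground truth for every stage; their defaults
are the package's study conditions.

* **Bulk compendia** (`BulkSimSpec`): 28 genes × 25 samples, one reference
  and one planted partner generated as exponentiated correlated Gaussians.
  The log-scale correlation ρ is calibrated in closed form from the
  bivariate-lognormal identity
  `r = (exp(ρσ²) − 1)/(exp(σ²) − 1)` so the *linear-scale* Pearson r
  matches the target (default 0.8, σ = 0.5) — RPKM-like data are
  right-skewed, so calibrating on the log scale alone would overstate the
  linear correlation. All other genes are independent lognormal noise with
  baselines spread over three orders of magnitude.
* **Single-cell counts** (`ScSimSpec` via `default_sc_spec`): 2000 cells in
  three equal cell types, 237 genes (a 12-gene planted module = substrate
  pair + candidate + 9 extras, 25 decoy candidates, 200 noise genes).
  Counts are negative binomial in the mean–dispersion form
  (variance μ + μ²/θ, θ = 2), sampled as a gamma–Poisson mixture. Module
  genes share a per-cell standard-normal latent factor z with multiplier
  `exp(latent_effect · z)` (default 1.5). Decoy baselines equal the planted
  candidate's within each cell type, so no stage can separate them by
  expression level alone. Module baselines share one per-type activity
  scalar — a co-regulated module rises and falls together across tissues
  (for collagen IV the subunits even share a promoter) — while noise-gene
  baselines are independent per type, giving genuine cell-type structure.
  One global seed expands into fixed-offset child streams so that, e.g.,
  adding genes cannot perturb cell-type sampling.
* **Assignment fixtures** (`make_assignment_fixture`): per-network
  gene→module maps with an exact planted number of candidate/substrate
  co-assignments, for testing the counting and permutation machinery
  directly.

Not simulated: ambient RNA, doublets, batch effects, gene-length bias,
UMI saturation, or realistic library-size variation. Passing tests
therefore demonstrate correctness of the statistical machinery under a
clean negative-binomial world with a planted low-rank signal, not
robustness to those artefacts. The synthetic gene panel (hundreds of genes)
is far smaller than a real transcriptome, which is why the pipeline-level
QC floor for synthetic runs is 10 detected genes rather than the real-data
default of 200.

## 6. Problem sizes and determinism

Default verification sizes, chosen to exercise every stage: 20 seeded
compendia for planted-partner recovery; one 2000-cell, three-type
single-cell run for metacell/network/co-occurrence properties; 10 seeds of
40-gene two-block fixtures for module recovery; 50,000 replicates for
Monte-Carlo-vs-oracle agreement and 10,000 for the co-occurrence call.
Every random draw flows from an explicit seed through `numpy`'s Generator;
reruns of the pipeline with one config produce byte-identical artifacts,
with checksums recorded in the run manifest.

## 7. Known limitations

* The static tree cut can split one planted module across height ties or
  absorb weakly correlated genes; it is deliberately simple, and pluggable.
* The scale-free fit is undefined on very small or degenerate panels
  (fewer than three usable connectivity bins); the power selection then
  falls back to the argmax with a warning rather than failing.
* The exact co-occurrence oracle assumes every candidate is present in
  every network's universe; the Monte Carlo path handles absent candidates
  (they contribute zero matches) but the oracle is only used where the
  assumption holds.
* Metacell overlap control is greedy; it guarantees the pairwise cap but
  not a maximal metacell set.
* Pooled (all-cell-type) correlations mix within-type and between-type
  signal; per-group correlations are available wherever that distinction
  matters.
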