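# Methods

## The module-first integration model

`holocorr` assumes that the biologically meaningful co-variation in each
omics layer is low-dimensional: features (genes, proteins, taxa,
metabolites) organize into modules driven by shared underlying processes,
and cross-layer biology expresses itself as correlation between module-level
profiles rather than between arbitrary feature pairs. The workflow therefore
has three stages, each with its own modelling assumptions.

### Stage 1 — module detection (weighted correlation network)

Given a complete samples × features matrix, the feature × feature
correlation matrix `R` (Pearson by default, Spearman optional) is
soft-thresholded into a weighted adjacency:

- unsigned (default): `A_ij = |R_ij|^β` — anti-correlated features can share
  a module, appropriate when a process up- and down-regulates targets;
- signed: `A_ij = ((1 + R_ij)/2)^β` — anti-correlation is treated as
  dissimilarity.

The topological overlap measure

    TOM_ij = (Σ_{u≠i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij)

replaces raw adjacency for clustering: two features are similar when they
are connected *and* share neighbours, which damps the effect of any single
noisy correlation. Computation is vectorized (`A@A` with diagonal
corrections); unit tests pin it to a naive O(n³) evaluation at 1e−12.

Modules are branches of the average-linkage dendrogram of `1 − TOM`, cut at
a fixed fraction (`cut_height`, default 0.99) of the tallest merge; branches
with at least `min_module_size` features (default 20) become modules,
labelled `M1, M2, …` by decreasing size, everything else is `unassigned`.
The static cut is deliberately simple and fully specifiable — the cut
interface is the natural extension point for adaptive tree cutters.
Modules whose eigengenes (first principal component of the standardized
member submatrix, sign-oriented to the mean member profile) correlate above
`1 − merge_cut_height` (default 0.25) are merged iteratively, most-correlated
pair first. `merge_cut_height = 0` disables merging entirely.

Each module is represented downstream by its **hub**: the member with
maximal intramodular connectivity `k_within`, ties broken lexicographically
on feature id (and logged). Hubs are extracted after merging, from the final
modules, and the hub table contains the hubs' *original* (untransformed)
profiles. The eigengene is used internally for merging only; the hub, being
a real feature, is the unit of interpretation and of all cross-layer
statistics.

**Choosing β.** The scan builds the adjacency for each candidate power
(default grid 1–20), bins the log10 node degrees into ≤ 10 occupied bins and
regresses log10 frequency on log10 mean degree; the fit R² is reported with
its sign flipped against the slope so a decaying degree distribution scores
positive. The smallest candidate reaching `rsq_target` (default 0.8) wins;
when none qualifies the best-fitting candidate is used with a warning. On
data that is genuinely not scale-free — including this package's own
latent-factor simulations, where every module member has the same expected
connectivity — the criterion is uninformative and the fallback is noisy. For
such data the package's documented choice is to fix `power = 6`, the
long-standing community default for unsigned weighted networks; the example
configs, the planted-data tests and the acceptance script all do this
explicitly.

Module detection refuses missing values and zero-variance features by name
rather than imputing silently: correlation-network behaviour under
missingness is ill-defined, and the right imputation is data-type-specific
and belongs upstream. A single-block implementation with a feature cap
(default 20 000) keeps memory quadratic and predictable; block-wise
decomposition is an optimization, not part of the method.

### Stage 2 — cross-layer correlation with significance control

All hub pairs between two aligned layers are tested:

- Pearson: product-moment r, two-sided p from `t = r·sqrt((n−2)/(1−r²))` on
  n−2 df;
- Spearman: Pearson on mid-ranks with the same t reference at every n (no
  silent switch to exact small-n tables);
- Kendall: τ-b with the tie-corrected normal approximation; exact
  enumeration only for n ≤ 8 without ties. |r| = 1 reports p = 0.

Missing data follow the three conventional policies: `all.obs` (refuse,
naming the first offending cell), `complete.obs` (casewise deletion over the
union of both layers' features, once), `pairwise.complete.obs` (per-pair
deletion, the default). Pairs with fewer than `min_pairs` (default 5)
complete observations, or left constant after deletion, are reported missing
— three-point correlations are noise, not evidence.

P-values are adjusted over the full matrix of one X×Y call as a single
family (Benjamini–Hochberg by default; Holm, Bonferroni, none). Pooling
across calls would make any one comparison's q-values depend on how many
other layers happen to be loaded. Metadata joins the same machinery after
encoding: numeric variables pass through, binary → 0/1, k-level categorical
→ k one-hot `var=level` indicators; metadata forms its own adjustment
family. Stars (\*, \*\*, \*\*\*) bracket the *adjusted* p at 0.05 / 0.01 /
0.001 — the conservative reading — and the raw p matrix is always written
alongside so users can re-annotate.

### Stage 3 — the integrated figure

The user designates one central layer. Its hubs are ordered by hierarchical
clustering (correlation distance `1 − r`, average linkage by default — the
metric matching the co-variation semantics of the whole workflow), displayed
as a modules × samples heatmap with its dendrogram, row-z scaled by default
so hubs with different dynamic ranges share a colour scale. Metadata
correlation blocks sit left, one block per other layer right; every block
must arrive in the central row order — a mismatch is an error, never a
silent reindex. Correlation colour scales are pinned to [−1, 1]. Samples are
grouped by a designated categorical annotation when one is given, otherwise
left in input order.

## Input handling

Tables are TSV/CSV with an `id` first field; orientation
(samples-in-rows / features-in-rows) must be declared — auto-detection is a
classic silent-corruption source and is deliberately not attempted. `NA`,
`NaN` and empty cells read as missing; `NA` is written. Sample alignment
takes the lexicographically sorted intersection across all tables (no layer
is privileged) and logs dropped ids per layer.

Built-in preprocessing is limited to what the integration itself needs:
low-prevalence filtering (a feature must be non-missing — and non-zero by
default — in at least `min_prevalence` of samples) and the centered
log-ratio transform for compositional layers (per sample:
`log(x_i + c) − mean(log(x + c))`, natural log). The default pseudocount is
half the smallest non-zero entry, added only when zeros are present; CLR
refuses negative or missing entries. The pipeline filters before CLR.
Anything heavier — CSS, VST, batch correction, imputation — is expected
upstream, following each data type's best practice.

## The simulator

`simulate_bundle` draws the minimal generative structure the workflow
assumes: per module one latent factor `f ~ N(0,1)` over samples; member
features `a·f + sqrt(1−a²)·ε` so the expected within-module feature
correlation is `a²` and the feature–factor correlation is `a`; background
features pure noise. Cross-layer couplings draw the two factors jointly
bivariate-normal with correlation ρ (the full coupling matrix is checked for
positive semidefiniteness at construction, naming an offending triple).
Numeric metadata ties to a factor as `b·f + sqrt(1−b²)·ε`; binary metadata
is `f > 0` flipped with probability `(1−b)/2`. Missingness is knocked out
completely at random. One master seed feeds named sub-streams (factors,
each layer in listed order, metadata, missingness), drawn module-major, so
appending a layer leaves earlier layers' draws bit-identical.

What the simulator does *not* emulate: count overdispersion and zero
inflation of real sequencing data, compositional closure (beyond an optional
softmax mode for exercising CLR), phylogenetic correlation among taxa, batch
effects, and non-Gaussian effect shapes. Passing tests therefore demonstrate
that the machinery recovers planted linear-Gaussian structure at realistic
sample sizes — not that any particular real dataset has such structure.

**Default study conditions.** The planted-data analyses use n = 40 samples,
modules of 40 features at loading a = 0.85, and 20–50 simulation seeds:
a few dozen samples is the typical scale of feeding trials and animal
cohorts this kind of tool targets, a² ≈ 0.72 within-module correlation
matches a clearly co-regulated pathway, and ρ = 0.8 a strong cross-layer
interaction. Under these conditions module recovery reaches ARI ≥ 0.9 in
≥ 90 % of seeds and the planted hub-pair coupling is detected (BH-adjusted
p < 0.05) in ≥ 90 % of seeds; both are recomputed, not quoted, by
`scripts/acceptance.py` and the test suite.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] before powering; adjacencies and TOM
  are symmetrized and clipped to [0, 1] with unit diagonal to absorb
  floating-point drift.
- Eigengene sign: oriented positive against the mean standardized member
  profile; when that profile vanishes (e.g. a module split into `z` and
  `−z`), orientation falls back to the first member, keeping the result
  deterministic.
- Hub ties (exactly equal `k_within`) break lexicographically and are
  logged.
- Dendrogram leaf order follows scipy's deterministic tie-break (the
  cluster holding the smaller original index leads each merge).
- A single-hub central layer yields a trivial ordering with no dendrogram;
  a zero-variance hub row under row-z scaling renders as zeros with a
  warning.
- `filter_low_prevalence` that would remove every feature, an empty sample
  intersection, and a non-PSD coupling graph are hard errors with
  actionable messages.
- Reruns into a populated output directory first remove the files listed in
  the previous manifest; an unreadable manifest aborts rather than
  overwrite.

## Known limitations

- The static height cut is cruder than adaptive tree cutters on nested or
  unevenly sized modules; the cut function is the intended extension point.
- Spearman p-values use the t approximation at all n; Kendall's exact
  enumeration is limited to n ≤ 8 without ties.
- Pairwise correlation cannot distinguish direct interaction from shared
  drivers; the output is a hypothesis map, not a causal network.
- Single-block network construction caps practical layer width (default
  20 000 features) — pre-filter wide layers upstream.
- Compositional effects: CLR mitigates but does not remove spurious
  correlation in strongly compositional layers; dedicated compositional
  correlation methods are out of scope.
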