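# Methods

## The model behind the pipeline

Marker-gene scoring of bulk tissue assumes each immune cell type k
contributes an (unobserved) abundance L[k, s] in sample s, and that a
marker gene g of that cell type has log2 expression

    x[g, s] = baseline_g + a_g · L[k, s] + ε,    ε ~ Normal(0, σ²)

Markers of the same cell type therefore co-vary across samples, with slope
a_g relative to the latent abundance. Two markers with equal slopes differ
only by an additive log2 offset; markers with unequal slopes respond
disproportionately and are weaker evidence of a shared cell-type signal.
Every statistic in the package is a consequence of this model.

### Pairwise similarity

    similarity(x, y) = 2·cov(x, y) / (var(x) + var(y))

Dividing the covariance by the arithmetic rather than geometric mean of the
variances makes the statistic slope-sensitive: for y = a·x + b it equals
2a/(1+a²), maximal (1) at a = 1, and by the AM–GM inequality
|similarity| ≤ |Pearson r| with equality iff var(x) = var(y). Variance and
covariance use the unbiased (n−1) estimators; with that choice
similarity(x, x) is exactly 1, which is the defining property of an ideal
marker pair (the n and n−1 conventions differ only by a common factor that
cancels, but we fix n−1 so the identity is exact and unit-testable).
Vectors shorter than 3 samples are rejected: the statistic is formally
defined at n = 2 but is pure noise there, and a length-2 input almost
always indicates a malformed matrix.

Zero-variance (flat) genes make the statistic undefined for a pair of flat
genes and uninformative otherwise. The scalar function raises on a fully
degenerate pair; the matrix assembler instead records flat genes in
`degenerate`, sets their rows/columns (including the diagonal) to 0 and
warns, so one flat probe cannot abort a catalog-wide run. Flatness is
detected with a relative tolerance (SD ≤ 1e-12·(1+|mean|)) because a
mathematically constant gene can acquire one-ulp wobble through float
centering.

### Marker selection

The selection rule is a pairwise threshold (default 0.6) on the similarity
among a cell type's candidates. A pairwise criterion does not by itself
determine which genes to keep, so two explicit aggregation modes are
implemented:

- `prune_mean` (default): iteratively remove the candidate with the lowest
  mean off-diagonal similarity until every remaining gene's mean meets the
  threshold. This mirrors how a coherent "block" emerges in a similarity
  heat map, and is the default because it tolerates one mediocre pair
  inside an otherwise tight block.
- `all_pairs`: the largest subset in which *every* pair meets the
  threshold (maximum clique of the thresholded similarity graph), with
  ties broken by higher mean similarity, then lexicographically. Candidate
  lists are short (≤ a dozen genes), so exhaustive search is exact and
  fast.

The two modes agree on clean single-block structures (property-tested on
planted-block simulations). If pruning leaves fewer than two genes the cell
type is reported `empty`; a single-candidate cell type passes through
flagged `single_gene` — retained but low-confidence, as for cell types
that are definable only by one marker (NK cells, Helper 1 T cells, CD45+).
Selection is fully deterministic, and raising the threshold can only
shrink the selected set (tested across a threshold grid).

### Concordance and its permutation test

    concordance(X) = uᵀ Cov(X) u / trace(Cov(X)),   u = (p^−½, …, p^−½)

A Rayleigh quotient, hence in [0, 1]: 1 when all p genes are perfectly
correlated with slope 1 (the covariance matrix is rank one along the
equal-weights direction), about 1/p for independent equal-variance genes,
and invariant to per-gene additive constants. The covariance uses the same
(n−1) estimator as the similarity.

The permutation test draws `n_permutations` (default 1000) random size-p
subsets from a pool — by default every endogenous gene of the matrix,
excluding housekeeping and control probes; whether the tested genes
themselves stay in the pool is configurable (default: they do, since the
null is "a randomly selected gene set of similar size"). The p-value is
the strictly-greater proportion r/n, a multiple of 1/n; an optional
(r+1)/(n+1) estimator avoids exact zeros at the cost of positive bias and
is off by default. A single seeded generator drives each call and the seed
is echoed in the result for audit.

Calibration: marginally over data realizations the test is calibrated
(type-I error ≈ α). Conditional on a single matrix, however, the p-values
of many gene sets drawn from the *same* matrix are correlated — whichever
genes happen to be incidentally correlated in that realization drag every
set containing them — so an empirical rejection rate measured on one
matrix fluctuates somewhat more than binomial sampling alone would
suggest. The packaged calibration check (200 sets of 5 genes against a
500-gene, 50-sample null pool) lands at 0.055 at α = 0.05.

### Scoring and group comparison

A cell score is the per-sample arithmetic mean of the marker genes' log2
values (a single-gene cell type's score is that gene's value exactly).
Relative abundance divides a score by the CD45+ (PTPRC) reference score —
the literal published convention, kept as the `ratio` default — or
subtracts it (`log_diff`), which is the standard log-scale normalization
and is invariant to global shifts; the mode is always recorded in output.
Group tables aggregate as (group-mean score) vs (group-mean reference),
while the t-tests run on per-sample relative scores.

Group comparison uses Welch's unequal-variance two-sided t-test (scipy),
the safer choice at the small group sizes typical of treatment cohorts
(n ≈ 6). Two groups that are both constant and equal report t = 0, p = 1
by convention. No multiple-testing correction is applied across cell types
by default; a Benjamini–Hochberg column is available behind a flag.

## Bundled catalogs

`pdac_cmg` (90 unique candidate genes, 23 cell types), `pdac_mgic` (55
selected markers, 22 cell types; plasmacytoid dendritic cells retained no
marker and drop out) and `nsolver_default` (60 genes, 14 cell types) are
shipped as TSV resources with per-gene provenance tags and optional
parent links expressing the cell-type family structure (e.g. Plasma B
cells → B cells). Eight cell types of `pdac_mgic` have no counterpart in
the default definitions. Gene matching throughout the package is
uppercase, whitespace-trimmed and exact — no alias resolution; catalog
genes absent from a matrix are dropped with a warning that lists them.

## Preprocessing

- `log2_transform`: log2(x + offset), offset 1 by default (avoids −∞ at
  zero counts); transforming an already-log2 matrix is an error rather
  than a silent double transform.
- `normalize_housekeeping`: per-sample scaling by housekeeping geometric
  means (each sample multiplied by mean-of-geomeans / its geomean). This
  is a documented approximation of content normalization as done by
  nSolver, not a parity implementation.
- `detection_filter`: keep genes above a threshold in at least a fraction
  of samples (boundary inclusive; 3 of 6 samples passes 50%). No universal
  background threshold exists for arbitrary matrices, so the threshold is
  explicit; for RCC data with negative-control probes,
  `negative_control_threshold` supplies mean + 2·SD of the negative
  controls as a conventional background estimate.

## The simulator

`simulate()` draws the latent-factor model directly on the log2 scale:
latents are standard normal (plus per-group shifts), markers add Gaussian
noise with `noise_sd` (default 0.1 log2 units — tight co-expression, the
regime the selection method assumes), decoy genes are independent draws
with unit SD around a uniform baseline in [6, 10] log2 units (so decoys
have spread comparable to a loading-1 marker and baselines typical of
well-expressed panel genes), and housekeeping genes use SD 0.05.
Generating on the log2 scale directly means linear-scale negativity cannot
arise. One latent per cell type, no cross-loading by default; an optional
`cross_loading` parameter induces the correlated-cell-type ambiguity seen
between, e.g., dendritic-cell and monocyte markers in real panels.

What the simulator does *not* emulate: count-level noise (negative
binomial mean–variance), compositional competition between cell types,
batch effects, or realistic gene–gene correlation beyond the planted
blocks. Passing tests therefore demonstrate correctness of the statistics
and the recovery behavior under the model's own assumptions, not
performance on real tissue.

The named fixtures (`fixture_suite`) fix these choices once:
`clean_block` (5 markers, 6 decoys, n = 50, noise 0.1) for selection
recovery; `null_pool` (500 independent genes, n = 50) for calibration;
`two_groups` (four cell types incl. a single-gene CD45+, n = 30, a +3
latent shift on T cells in the treated group — chosen so the planted
effect is unambiguous against the reference-subtraction noise at 15
samples per group) for comparison sanity; `degenerate` (zero-noise,
loading-0 blocks) for flat-gene handling.

## Problem sizes in the packaged checks

The test suite and the acceptance script run at desk scale: recovery over
100 simulations of 11 candidates × 50 samples, calibration over 200 null
sets × 1000 permutations against a 500-gene pool, and closed-form checks
on vectors of length ≤ 50 000. These sizes give stable estimates (binomial
half-width ±0.03 on the calibration rate) while keeping the whole suite
under half a minute.

## Known limitations

- Relative scores only: nothing here estimates absolute cell counts, and
  expression cannot distinguish cell number from per-cell activity.
- `ratio`-mode relative abundance divides two log2 quantities, which
  depends on the global expression offset; `log_diff` is provided for
  analyses that need shift invariance.
- Single-gene cell types and sets whose similarity falls below threshold
  are flagged, not hidden — their interpretation is inherently weaker.
- The permutation pool and tie handling are explicit design choices
  (documented above) since panel-analysis conventions vary.
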