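# Methods

## The problem

In droplet single-cell RNA-seq, cell-free ("ambient") transcripts released
by dead or dying cells are co-encapsulated into every droplet, so empty
droplets carry counts and real cells carry a contaminating admixture.
`ambiquant` quantifies this contamination on a continuous scale directly
from the *unfiltered* barcode × gene UMI count matrix, before any cell
calling — six contamination metrics, four conventional QC summaries, and
one overall score per dataset.

## Pre-metric scaling

Barcodes are sorted by descending total UMI count. The real-cell number is
estimated as the first inflection (knee) of cumulative counts versus
log10(rank), or supplied by the user. The dataset is then truncated to the
top `multiple × n_cells_est` barcodes (default multiple 4), which makes
datasets with different numbers of encapsulated cells and empty droplets
comparable: roughly a quarter of retained barcodes are putative cells. Both
rank and cumulative count are normalized to (0, 1].

**Knee detection.** The signed perpendicular distance between the
normalized cumulative-vs-log-rank curve and the chord joining its endpoints
is smoothed with a centred moving average (window 5); the first local
maximum is taken and then refined to the unsmoothed maximum within one
window. The refinement matters on sharp step-like profiles, where smoothing
alone displaces the peak by a few ranks. Zero-count barcodes stay in the
curve: they form the flat tail that anchors the knee when a dataset has
essentially no ambient counts. If no point of the smoothed curve rises
above the chord by more than 1e-3 (e.g. near-uniform totals, or heavily
contaminated data whose curve hugs the diagonal), the estimator emits a
low-confidence warning and falls back to `n_positive_barcodes / multiple`,
which leaves the conventional one-quarter-cells geometry intact.

## Curve-geometry metrics

With the diagonal `y = x` joining origin and endpoint of the normalized
curve, the vertical secant distances are `d_i = c_i − x_i` (clamped at 0
against float noise; they are non-negative for any concave curve). Metrics,
each inverted so that higher = more contaminated:

- inverted max secant distance `= 1 − max_i d_i` ∈ [0, 1]
- inverted secant sd `= 0.5 − sd(d)` ∈ (0, 0.5], with sd the *population*
  standard deviation. The 0.5 bound holds for every normalized concave
  curve; empirically the supremum over adversarial curves is 1/√12 ≈ 0.289
  (a step curve's distances fall linearly), so the bound is conservative.
- inverted AUC percentage `= 2 × (1 − AUC)` ∈ [0, 1], AUC by the
  trapezoidal rule on the origin-prepended normalized curve. On the
  normalized curve the minimal circumscribing rectangle (number of barcodes
  × maximum cumulative count) has area 1, so the AUC percentage equals the
  AUC; a diagonal curve gives AUC 0.5 → metric 1, a step curve AUC → 1 →
  metric 0. Computing instead on the raw curve with the explicit rectangle
  area is algebraically identical and is used as an independent oracle in
  the tests.

## Slope-distribution metric

The slope of the cumulative curve at rank i is the barcode's own normalized
total, `c_i − c_{i−1}`. Slopes are histogrammed into 100 equal-width bins
over [min, max] (option: [0, max]); each bin's frequency is multiplied by
its midpoint, and the scaled values renormalized to sum 1, which restores
numerical weight to the sparse high-slope (cell) bins. The cell/empty
threshold is `median(slopes) + population sd(slopes)`, computed on the raw
(unbinned) slopes: the truncation scheme guarantees a dominant low-slope
mode, the median estimates its centre robustly, and for a Gaussian the
median+1σ cut keeps Φ(1) ≈ 84% of the mass on the left (verified by a
Monte-Carlo self-test). The **empty-droplet scaled slope sum** is the
scaled mass in bins with midpoint ≤ threshold (ties count as empty; this
affects only knife-edge inputs). All-identical slopes are flagged
degenerate with the whole mass below threshold (metric 1). The metric is
invariant to scaling all counts by a positive constant, since slopes and
threshold are computed on the normalized curve.

## Ambient genes and standard QC

Ambient transcripts contaminate all droplets, so an ambient gene should be
detected in nearly every retained barcode; allowing for sampling dropout,
genes with dropout rate strictly below 2% (configurable) across the full
truncated barcode set are called ambient. Over the top `n_cells_est`
barcodes (the rank-based cell proxy — probabilistic cell callers are
deliberately out of scope), the percentage of each cell's UMIs in ambient
genes and the mean ambient UMI count per cell are computed, along with
standard summaries: mean UMIs/cell, mean detected genes/cell, and mean
percent mitochondrial counts (gene symbols matched by prefix, default
`mt-`/`MT-`, configurable per species). The ambient-gene count and
percentage are intentionally depth-*sensitive* (detection in ≥98% of
droplets needs depth), unlike the four curve-shape metrics, and the tests
assert both behaviours.

## Overall score

Five bounded features — empty-droplet slope sum, inverted max secant,
doubled inverted secant sd (mapping [0, 0.5] to [0, 1]), inverted AUC
percentage, and percent counts ambient as a fraction — are combined
linearly with non-negative weights summing to 1, clamped to [0, 1]
(clamps > 1e-6 warn). Weights come from a PCA over a simulated calibration
sweep: the six metrics (the five features plus the ambient-gene count,
which is informative but unbounded and depth-sensitive, so it gets no
weight) are standardized and decomposed; the absolute first-component
loadings of the five features, renormalized, are the weights. Because every
metric co-increases with the ambient level, PC1 captures the shared
contamination axis (≈90% of variance on the default sweep) and its
loadings share a sign — a sweep where they do not (e.g. a single ambient
level) is rejected as degenerate. The shipped default model was derived at
10 log-spaced ambient levels 5–4900 × 50 replicates of full-size datasets
(seed 20260925) and is versioned JSON; `ambiquant calibrate` re-derives it.
Weight choice sets the scale of the overall score, so scores are comparable
within one score model; per-metric values are model-independent.

## The droplet simulator

The simulator is the calibration and validation substrate, emulating an
unfiltered dataset as follows:

- **Sizes.** Centres: 2000 real cells, 12000 droplets, 5000 biological
  UMIs per cell. With `randomize=True` (default) the three dataset-level
  sizes are drawn from truncated normals with 10% CV (floor 1); per-cell
  biological totals always vary with 10% CV around the (possibly drawn)
  centre. The distribution family and CV are package choices; only the
  centres are prescribed by the method.
- **Expression profiles.** Each of K clusters (default 5) mixes a shared
  heavy-tailed housekeeping profile (weight 0.5, Dirichlet α = 0.05 over
  all genes) with a cluster-specific Dirichlet (α = 0.3 background, α = 30
  on a distinct 5% marker block). The housekeeping component mirrors the
  top-heavy expression of real transcriptomes and lets ambient genes emerge
  gradually as contamination rises; without it the ambient profile is
  near-flat and the gene-level metrics jump from zero to hundreds at a
  single level.
- **Ambient counts.** The ambient profile is the expression-weighted
  average of the cluster profiles. Every droplet (cell or empty) draws an
  ambient total from a lognormal with arithmetic mean equal to the
  dataset's ambient level and log-sd 0.5 (shape parameter is a package
  default), then distributes it multinomially over the ambient profile.
  Levels 5–4900 against the 5000-UMI biological centre span noise-to-signal
  ratios ~0.001 to ~0.98.
- **Pairing across levels.** The RNG stream is consumed in a fixed order
  with all biology (and the droplet shuffle, and the lognormal factors)
  drawn before any level-dependent quantity, and the ambient total is
  `level × exp(σz − σ²/2)` with pre-drawn z. Two simulations sharing a
  seed but differing in ambient level therefore share identical biology —
  common random numbers that make paired level comparisons nearly
  noise-free. The sweep helper fans out seeds as
  `SeedSequence([base, level_index, replicate_index])`, stable across runs
  and platforms.
- **Downsampling.** Sequencing depth is emulated by drawing exactly
  `round(fraction × total)` UMIs without replacement across all nonzero
  entries (multivariate hypergeometric), so fraction 1 is the identity; a
  with-replacement multinomial option reproduces the common
  resampling-based downsampler.

**What the simulator does not model:** doublets, barcode swapping, UMI
collisions, per-gene technical noise beyond multinomial sampling, batch
structure, or real cell-type hierarchies. Passing the simulation-based
tests therefore shows the metrics respond correctly to *ambient admixture
under multinomial sampling*, not that they are unconfounded by every real
artefact.

## Validation problem sizes

The packaged validation suite uses scaled-down but representative sizes:
the monotonicity suite runs 10 log-spaced ambient levels 5–4900 with 50
paired replicates each at full default dataset size; the depth suite
downsamples one full-size level-1000 dataset to fractions 0.2–0.8; the
secant-sd bound is searched over 10^5 random concave curves of 3–1000
points plus hand-built extremes; the Gaussian threshold self-test uses 10^6
draws; unit tests use miniature datasets (hundreds of droplets). Weight
stability under replicate doubling is ≤ 0.02 per feature at these scales.

## Known limitations

- The knee estimator targets the *first* inflection; on heavily
  contaminated data there may be none, and the fallback (all positive
  barcodes / multiple) then sets the cell proxy. A user-supplied expected
  cell number always takes precedence and is the recommended path when the
  encapsulated cell count is known.
- The rank-based cell proxy over-counts cells when many empty droplets
  outrank true cells (severe contamination); the gene-level percentages
  then describe the proxy set, not true cells.
- Overall-score values are tied to the shipped weight model's provenance;
  compare scores only under the same model.
- Exactly uniform counts, all-zero matrices and sub-3-barcode inputs are
  rejected or flagged rather than scored silently.
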