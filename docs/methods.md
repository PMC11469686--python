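# Methods

This note documents the models and procedures permap implements, the
defaults and why, the numerical choices, and the limits of what the
bundled synthetic screens can demonstrate.

## Data model

A screen arrives as a *unit table*: one row per perturbation unit (a
cell in pooled single-cell screens, a well or guide in arrayed screens)
with numeric feature columns and metadata columns for the perturbation
label, batch label, control flag and — for non-controls — an expressed
flag. Column roles are declared through a schema mapping because source
datasets disagree on conventions. Rows with missing feature values are
rejected at read time rather than imputed. Gene labels are matched
case-sensitively (symbols such as C18orf21 are case-meaningful), and
controls are identified only by the control flag, never by label
matching. Batch is an opaque label; its granularity (plate, run,
experiment, GEM group) is the caller's choice.

## Map building (EFAAR)

Stages execute in the order filter → embed → align → aggregate → relate.

**Filter.** Three rule kinds, applied in declared order with removal
counts logged: a robust Gaussian outlier filter (elliptic-envelope fit
on selected columns; units in the lowest-density fraction removed;
default contamination 1%, the conventional rate for intensity-artifact
removal), an inclusive range filter (e.g. cell counts in [50, 350]), and
a column-prefix drop (e.g. image-level feature columns, which carry
batch-correlated signal rather than per-cell phenotype). Filtering the
entire dataset away is an explicit error.

**Embed.** PCA with a per-batch center/scale of the inputs beforehand
(configurable off), fit on all units or controls only. All `k`
components are returned in variance order; explained-variance fractions
go into provenance. Component signs are fixed so each component's
largest-magnitude loading is positive — PCA is sign-ambiguous and this
convention makes outputs reproducible across linear-algebra backends.

**Align.** Two methods:

- *center_scale*: shift/scale each feature by the reference units'
  (default: controls') mean and standard deviation, per batch or
  globally. Fewer than two reference units in any batch, or a
  zero-variance feature, is an error naming the offender.
- *tvn* (typical-variation normalization): (1) center/scale every
  feature to global control statistics; (2) fit PCA on controls only and
  project all units — the control-fit PCA is capped at n_controls − 1
  components, the rank a centered fit can attain; (3) center/scale the
  component scores to global control statistics; (4) per batch, CORAL:
  center by the batch-control mean and whiten by the batch-control
  covariance via the inverse principal square root. The recoloring
  target is the identity, since all batches are being mapped into one
  common control frame. Batch-control means are re-centered in step 4
  because covariance matching alone would leave additive batch offsets
  in place. Covariances get an ε·I ridge with ε = 1e-6 × mean diagonal
  before inversion; small per-batch control counts otherwise make them
  ill-conditioned, and a covariance still singular past the ridge is an
  error naming the batch.

**Aggregate.** Coordinate-wise mean of each non-control perturbation's
aligned units; replicate counts are recorded. Replicates are whatever
rows share a perturbation label — no guide-aware stratification.

**Relate.** Full symmetric cosine-similarity matrix. A zero-norm
aggregated vector is an error rather than a silent NaN: it indicates
degenerate upstream filtering.

Presets: `raw-cs` (per-batch control scaling), `raw-tvn`, `pca`
(per-batch z-score + PCA, no alignment), `pca-cs`, `pca-tvn`.

## Perturbation-signal statistics

**Consistency (avgsim).** Mean cosine over all unordered replicate
pairs, i ≠ j. The literal all-pairs form including i = j would give 1/n
rather than 0 for mutually orthogonal replicates, contradicting the
statistic's intended zero point, so self-pairs are excluded by default;
`include_self=True` restores the literal form. All pairs are weighted
equally regardless of batch composition.

**Magnitude (energy distance).** The standard two-sample energy distance
with full double sums and Euclidean norms; nonnegative, zero iff the
distributions coincide. All three terms are computed through the same
pairwise-distance code path so that E(X, X) cancels to exactly zero in
floating point.

**Significance.** Non-parametric: the statistic of each expressed gene
is compared to the empirical null formed by the identical code path over
unexpressed genes, p = max(#{null ≥ observed}, 1)/K, ties counting as
exceedances and the clamp keeping p ≥ 1/K. At least K = 1000 null genes
are required by default (configurable floor); the distributional shape
of these statistics is not well approximated by any convenient
parametric family, which is why no parametric test is offered. Raw
p-values are thresholded (default α = .05) without multiplicity
correction — the benchmark reports population fractions, not per-gene
discoveries.

## Relationship benchmarks

**Recall.** Percentile cuts are linear-interpolation empirical
percentiles of the off-diagonal upper-triangle similarity values (each
unordered pair once — recall is identical under ordered-pair cuts, but
logged cut values refer to the unordered list). Predicted links are
strictly below the lower or strictly above the upper cut, so ties at the
cut are not predicted. Annotated pairs with either gene absent from the
map are dropped from the denominator; self-pairs never enter. Zero
evaluable pairs is an error, not a recall of 0. The expected recall of a
random map is 2·tail·100 (10% at the default 5% tails).

**Noise sensitivity.** For each sampling level m, each non-control
gene's replicate pool is subsampled to at most m units (genes with fewer
keep all, logged), controls are kept in full since they anchor
alignment, the map is rebuilt and all recalls recomputed; mean and sd
over repeats (default 3) are reported. One master seed spawns one child
stream per (level, repeat), so adding levels never shifts existing
draws.

**Complex identification.** For each cataloged cluster with ≥ 10 genes
in the map: within-distribution = cosines of all unordered member
pairs; cross-distribution = cosines of all (member, non-member) pairs;
two-sample KS statistic with the two-sided asymptotic p-value (pair
counts here are in the hundreds to tens of thousands, where the
asymptotic formula is accurate; an exact option exists via `ks_method`).
Identified ⇔ p < .01. Clusters may overlap.

**Neighbors and enrichment.** Top-k cosine neighbors (default k = 25),
self excluded, ties broken lexicographically for determinism. Enrichment
is an upper-tail hypergeometric test with the map's gene universe as
background; only terms with ≥ 10 genes in the universe are evaluated,
and the Bonferroni factor is the number of evaluated terms, not the
collection size.

## Annotation handling

All pair sets are canonical unordered pairs (lexicographically smaller
gene first), deduplicated, self-pairs dropped on load. Scored edge lists
keep edges at score ≥ threshold (e.g. 950 on a 0–1000 interaction-
confidence scale). Complex catalogs expand to the union of within-
complex pairs. An optional alias table handles symbol reconciliation
across sources; none is applied by default.

## Synthetic-screen generator

Each expressed gene g has a true effect vector θ_g. Genes planted in a
complex share a latent direction u_c: θ_g = effect_scale·(u_c +
0.25·ε_g); other expressed genes get independent Gaussian effects;
unexpressed genes have θ = 0. A unit of gene g in batch b is

    x = A_b (θ_g + η) + μ_b,   η ~ N(0, noise_sd²·I),

with μ_b a per-batch offset (scale `batch_shift_scale`) and A_b =
R·diag(s_b)·Rᵀ a per-batch scaling, log-normal per feature (spread
`batch_scale_spread`), applied in a fixed orthogonal frame R shared
across batches. Controls are the same with θ = 0. Placing the scaling in
a latent frame rather than the observed feature frame is deliberate:
real batch scalings are correlated across measured features, an
observed-frame diagonal scaling would be removed exactly by per-feature
centering/scaling (making CS and TVN indistinguishable), and the latent
frame keeps the artifact affine — the model class TVN is built for — so
the TVN > CS > unaligned ordering is a genuine property of the generator
rather than a sampling accident. Replicates are assigned to batches
uniformly at random. All draws come from named substreams of one master
seed, so outputs are bit-reproducible and adding a draw site does not
shift existing streams.

Defaults (1000 expressed + 1000 unexpressed genes, 20 complexes of 12,
32 dims, 4 batches, 4 replicates/gene, 32 controls/batch, effect scale
1.0, noise sd 1.0, offset scale 1.0, scale spread 0.3) describe a
mid-sized arrayed screen with visible but not overwhelming batch
structure. Two named regimes recur in tests and the acceptance script:
a *null screen* (effect scale 0, no batch artifacts) for calibration,
and a *strong-batch screen* (effect 0.4, noise 1.0, offset 8.0, spread
1.5, 6 batches) where alignment choice decides map quality. Problem
sizes there (200–300 genes, 16–24 dims) are chosen so the full suite
runs in seconds while leaving the compared effects far above
Monte-Carlo noise.

What the generator does **not** emulate: non-affine batch effects,
heavy-tailed or structured measurement noise, guide-level biology
(on/off-target variation), plate-position effects, proximity bias, or
realistic image/count generation. Passing benchmarks on these screens
therefore shows the machinery is correct and the alignment ordering
holds in the affine-artifact regime; it does not certify performance on
any real dataset.

## Known limitations

- TVN assumes controls are representative of typical (non-perturbation)
  variation in every batch; few or atypical controls degrade it, and the
  per-batch control count lower-bounds the usable PCA rank.
- The KS identification p-value treats pair similarities as independent
  samples, which pairs sharing a gene are not; it is a ranking device,
  as is standard, not a calibrated error rate.
- Recall compares maps only at fixed tails; it says nothing about
  calibration of similarity magnitudes between maps.
- Deep-learning embeddings (CNN image features, scVI latents) are
  accepted as precomputed inputs; permap does not train them.
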