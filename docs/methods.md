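# Methods

This note documents the models, procedures, and numerical choices behind
repgeom, and what its synthetic-data tests do and do not establish about
real data.

## Representational dissimilarity matrices

All pipeline stages exchange RDMs: square, symmetric, zero-diagonal,
finite matrices with unique condition labels. A single vectorization
routine — lower triangle excluding the diagonal, row-major — is used for
every fit, correlation, and resampling operation, so neural and model
vectors can never be silently misaligned. Validation happens at
construction (tolerance 1e-8 for symmetry/diagonal, then exact
symmetrization), not at use.

### Neural split-data RDMs

Response patterns arrive as condition x unit matrices, one per subject per
session, and are z-scored per unit across conditions (sample sd, ddof=1;
constant-profile units are dropped with a logged warning because their
z-score is undefined). The cross-session correlation matrix `M_ij =
corr(x_i^(1), x_j^(2))` is symmetrized and converted to dissimilarity
`1 − (M+Mᵀ)/2` with the diagonal forced to zero. The raw diagonal — the
split-half reliability of each condition's pattern — is preserved in
metadata and excluded from all model comparisons; a `negative_reliability`
flag marks pathological sessions. Because the per-model fits are
rank-based, the affine choice `1 − r` versus `−r` is cosmetic; it is fixed
here once.

### Behavioral arrangement RDMs

Participants arrange stimulus subsets in a circular arena; screen distance
encodes dissimilarity. The subset designer draws each candidate subset as
the head of a fresh permutation of the stimulus list and keeps, among
`n_candidates` candidate designs (default 1000), the one covering the most
distinct unordered pairs (first occurrence wins ties — stable under a
fixed seed). Aggregation averages each pair's Euclidean screen distances
over all sets observing it, each observation weighted equally; a full-set
record guarantees coverage, and an uncovered pair is a hard error naming
the pair. Coordinates stay in native screen pixels. An optional per-record
RMS-distance normalization flag exists for arrangements made at
incommensurate zoom levels; it is off by default because plain averaging
is the documented procedure, and it is never applied silently.

### Gaze RDMs

Raw trajectories (1000 Hz, 2500 samples per 2.5 s trial) are preprocessed
in three steps: (1) invalid (blink) spans are linearly interpolated from
flanking valid samples, with edge spans extended from the nearest valid
sample; (2) x and y are independently median-filtered with a centered
rolling window (84 ms -> 84 samples at 1000 Hz) that shrinks at the
boundaries; (3) the series is decimated to 60 samples (one per 24 Hz video
frame) by taking the sample nearest each frame time. A trial with no valid
sample raises a dedicated exclusion signal. Dissimilarity between two
stimuli is the sum over the 60 frames of the Euclidean distance between
gaze positions — translation-invariant, scale-covariant. Participants
whose block-wise gaze RDMs correlate below r = .1 on average (Pearson,
over lower-triangle vectors, all block pairs) are excluded; survivors'
RDMs are averaged within, then across participants.

### Semantic and feature RDMs

Each stimulus carries annotator-assigned labels split into verbs and
nonverbs, each label with a pretrained embedding vector. The per-class
mean vector represents the stimulus; RDM entries are cosine distances
between mean vectors (invariant to uniform positive rescaling of the
embeddings). Inter-annotator agreement is the per-stimulus Pearson
correlation between the two annotators' mean vectors, summarized by mean
and sd across stimuli. Generic feature spaces (e.g. motion-energy outputs,
consumed as precomputed vectors) go through the same machinery with a
choice of correlation, cosine, or Euclidean distance.

## Model comparison

- **Per-model fits** are Spearman correlations (average ranks for ties)
  between vectorized RDMs.
- **Joint fits** rank-transform and standardize (mean 0, sd 1) the
  response *and* all predictors before OLS with intercept, reporting
  in-sample R². Ranking the response as well as the predictors is a
  deliberate choice: it makes a single-model joint fit equal the squared
  Spearman fit to 1e-10, so the two analyses are mutually consistent.
  Exactly collinear predictors are an error in `joint_fit` (with the
  dependent models named via QR diagnostics).
- **Variance partitioning** computes `unique R² = full R² − nested R²`,
  the nested regression dropping the partition's models. The partitioning
  path tolerates exact collinearity (minimum-norm least squares; R² is
  still well defined) so that, e.g., a duplicated predictor provably
  contributes zero unique variance. In-sample OLS monotonicity guarantees
  unique R² ≥ 0 up to floating point; tiny negatives are never clamped in
  stored values, only in reports.
- **Noise ceiling**: leave-one-out intersubject Spearman correlation of
  RDMs, averaged on the Fisher-z scale and back-transformed. Group means
  of correlations are always Fisher-z averaged; R² values are averaged on
  their native scale (no variance-stabilizing transform is standard for
  R²). The ceiling-indexed share of variance is `100 · R² / r_ceiling²`.

## Statistical evaluation

All resampling p-values use the add-one convention `p = (1 + #{null ≥
observed}) / (n_resamples + 1)` with ties counting against rejection —
valid by construction, never zero, floored at `1/(n_resamples+1)`.

- **Sign-flip permutation** (per-model correlations): each permutation
  independently flips each subject's sign; statistics are Fisher-z
  averaged and back-transformed. Exact under the null of a symmetric
  zero-centered subject distribution.
- **Re-centered bootstrap** (R² statistics): R² is positively biased, so
  sign-flipping would be anticonservative; instead subject values are
  resampled with replacement and the distribution of bootstrap means,
  re-centered by the observed mean, serves as the null.
- **Condition-label permutation** (single-RDM fits, ROI-style): one shared
  permutation shuffles the model RDM's rows and columns per iteration.
- **Bootstrap intervals**: percentile intervals resampling subjects, or
  subjects and stimuli jointly. Stimulus resampling draws condition
  indices with replacement and rebuilds each RDM on the resampled index
  set; pairs formed by a condition and its own duplicate have no defined
  dissimilarity and are excluded from the vectorization. A fully
  degenerate resample is redrawn under a bounded, logged retry budget.
- **FDR**: Benjamini–Hochberg step-up (via statsmodels), applied map-wise
  across neighborhoods within one model's map, default q = .001.

## Design generation

The experiment's 20 trial types (18 stimulus categories, null fixation,
semantic probe) are ordered by a serially balanced sequence: a cyclic
sequence of n² = 400 trials in which every ordered pair of types —
self-pairs included — occurs exactly once among the cyclic adjacencies,
i.e. an Eulerian circuit of the complete directed graph with self-loops
(equivalently, an order-2 de Bruijn sequence over 20 symbols). The
unconstrained generator is a randomized Hierholzer construction. The
session builder additionally needs every type to occur exactly n/n_runs
times per run, so that each category's 5 exemplars can be used exactly
once per run; translate-based algebraic constructions (Williams terraces,
reversal interleaving) cover all ordered pairs but provably cannot chain
into a single circuit with the required self-pair junctions, so the
run-balanced variant is a randomized depth-first search with per-run
capacity constraints and a restart budget (typically ~0.2 s for n = 20,
4 runs; a `GenerationError` after 200 restarts has not been observed).

Probe trials that would follow a fixation or another probe (each forced
exactly once per sequence by the balance structure) are replaced by
fixation trials; the repair is a single idempotent left-to-right pass.
Each run is prepended with the previous run's last three trials (the final
run's, for run 0) drawn from a separate per-category preparatory exemplar
pool, so no exemplar repeats within a run.

Interstimulus intervals are `min + truncated-exponential` draws (floor
2 s, mean 2.5 s, truncation at 4 scale units), rescaled so each run's ISIs
sum exactly to the null-time budget — fixing run duration at 5 s lead +
3 prepended trials (15 s) + 100 x 2.5 s stimuli + 250 s ISI + 15 s trail
= 535 s. The rescaling preserves the exponential decay shape approximately.
Among `n_candidates` candidate schedules the one maximizing estimation
efficiency `e = 1/trace(C (XᵀX)⁻¹ Cᵀ)` is kept, with X built from
canonical double-gamma HRF-convolved 2.5 s boxcars for every non-fixation
type (fractional TR-bin coverage, 1 s sampling grid — the acquisition TR;
at these durations coarser grids shift scores monotonically without
changing rankings) and C the identity over modeled types. The session
builder defaults to 100 candidate schedules per run, a pragmatic default
for interactive use; the standalone onset generator defaults to 1000.

## Synthetic data and what it shows

The generator emulates the study's layout — 23 subjects x 2 sessions x 90
conditions (18 categories x 5 exemplars) — with planted ground truth:

- **Model RDMs**: category-structured (within-category distances
  stochastically below between-category), sociality-block, and
  unstructured (Euclidean distances of random 5-D Gaussian points) kinds;
  candidates are redrawn until all pairwise Spearman correlations are at
  most 0.8 (configurable), and an unsatisfiable request exhausts a retry
  budget and fails loudly.
- **Response patterns**: the target similarity is `S = Σ_k w_k (1−D̂_k)`
  over min-max-rescaled models, repaired to a valid correlation matrix by
  eigenvalue clipping and diagonal renormalization (the simplest repair
  preserving rank structure; all-zero weights plant the identity). Each
  unit's condition profile is an independent MVN(0, S) draw; independent
  N(0, σ²) noise is added per session. For the raw draws the expected
  cross-session correlation is exactly `S_ij/(1+σ²)`, and the convergence
  experiment verifies this elementwise to ±0.02 at 50,000 units for
  σ ∈ {0, 1}. The analysis path then z-scores profiles per unit; note that
  this re-centers profiles across conditions and shifts correlations by
  the row means of S (~0.2 for a category-structured S), which is why the
  generative law is checked on raw patterns while the z-scored path is
  validated by parameter recovery instead — rank-based fits are
  insensitive to the shift.
- **Arrangements**: subsets are embedded by classical 2-D metric MDS
  (double-centering + top-2 eigenvectors) with isotropic Gaussian jitter
  added in embedded coordinates. A 2-D-embeddable planted RDM therefore
  round-trips exactly at zero jitter; the Gaussian-jitter noise model is a
  stand-in, not a claim about real arrangement behavior.
- **Gaze**: AR(1) random walks pulled toward stimulus-specific attractor
  points (shared across blocks and participants via a stimulus-keyed
  substream), 2500 samples at 1000 Hz, with optional single-blink spans.
- **Annotations**: 2–5 verb and 3–6 nonverb vectors per stimulus around
  category-level class means in 300 dimensions; annotator 2 is a noisy
  copy of annotator 1.

All randomness flows from one root seed through named CRC32-keyed
substreams, so identical seeds give bitwise-identical outputs and adding a
simulator never perturbs existing draws.

**Planted-truth experiments** (in `repgeom.validation`, backing the test
suite and the reproduction script): the generative-law convergence check
above; dominant-model recovery — across 200 simulated neighborhoods
(20 subjects, 500 units, σ = 0.5, dominant weight 0.7 against 0.15
backgrounds, the dominant model cycling across neighborhoods), the planted
model must win the group Spearman ranking in ≥95% and the unique-R²
ranking in ≥90% of neighborhoods; and sign-flip calibration — on 2000
null cohorts (20 subjects, values N(0, 0.2), 1000 permutations) the
rejection rate at α = .05 must fall inside the exact binomial 99% interval
around the discrete level `⌊α(B+1)⌋/(B+1)`.

Passing these shows the pipeline is internally correct and statistically
calibrated under its own generative assumptions — Gaussian unit profiles,
isotropic session noise, exactly shared geometry across subjects. It does
not show that real cortical data meet those assumptions, that real
behavioral or gaze noise is Gaussian, or anything about preprocessing
upstream of the response patterns (GLM estimation, alignment), which this
package deliberately consumes as inputs.

## Problem sizes and defaults

Analysis constants default to the study's values: 10,000 permutations and
bootstrap iterations, FDR q = .001, gaze reliability threshold r = .1,
84 ms median window, 60 output samples, 12 subsets of 30 from 90 stimuli
chosen among 1000 candidates. The validation experiments use the sizes
stated above; the test suite exercises smaller instances (4–8 conditions,
reduced resampling counts) chosen so every contract is still exhaustively
checkable against brute-force oracles.

## Known limitations

- Searchlight geometry is consumed as an explicit neighborhood map; no
  surface or volume handling is included.
- No cross-validated or GLS/whitened RDM regression variants; the
  in-sample OLS analysis is implemented as specified.
- The run-balanced sequence generator is stochastic-search based; its
  runtime is random (restart-bounded), not worst-case guaranteed.
- Stimulus-resampling bootstrap supports statistics expressible on
  (masked) pair vectors; arbitrary RDM functionals would need the callback
  extended.
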