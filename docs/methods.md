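# Methods

## The measurement model

The toolkit analyses *hand-localization error maps*: a participant
places their unseen hand under each of 100 visual targets laid out as a
5 × 20 lattice on a 48.76 × 26.96 cm workspace (near edge 20 cm from
the body), and the registered hand position is compared with the target.
The error vector at a target is **hand − target** (tail at the target,
head at the hand), with components x_e (mediolateral, positive
rightward) and y_e (depth, positive away from the body).  A session's
map is the 2 × 5 × 20 array of these vectors, reported in cm (mm
internally, converted once at the map boundary).

Targets sit at *cell centers*: spacing = extent/count
(24.38 mm between columns, 53.92 mm between rows), which is the only
convention consistent with those spacings on a 487.6 × 269.6 mm
workspace.

Summary statistics:

- **mean error magnitude** — mean over targets of ‖(x_e, y_e)‖;
- **regional means** — left/right split the 20 columns 10/10 at the
  midline; near = rows 1–3 (closest to the body), far = rows 4–5;
- **error reduction** — 100 × (error₁ − errorᵢ)/error₁ relative to
  session 1;
- **direction-bias test** — on session-averaged maps, the count of
  subjects whose component is positive at each target is referred to the
  exact one-tailed binomial tails against p₀ = 0.5 at each side.  For
  n = 26 the criticals are 18 (upper) and 8 (lower).  One-tailed tails
  are used because those are the counts that an exact test at α = 0.05
  yields for n = 26 (a two-tailed construction would give 19/7).  Ties
  (a component exactly zero) count as not-positive; with continuous data
  this has probability zero.

## Idiosyncrasy statistics

For a session pair (A, B) and n subjects, similarity values are
computed for the full n × n pairing matrix of maps:
the n same-subject values are the *within* pool, the n(n−1) ordered
cross-subject values the *between* pool (for n = 26: 26 and 650
values).  Two metrics are provided:

- **correlation** — Pearson r over the 200 jointly flattened error
  components.  Joint flattening (x then y) yields a single coefficient
  per map pair; zero-variance maps raise an error rather than produce a
  silent NaN.
- **distance** — the Euclidean norm of the 200-component difference
  divided by 100.  This is the scaled-norm rule as used in the field,
  kept verbatim even though it is not literally a per-target mean.

The within/between comparison uses Welch's unequal-variance t-test on
Fisher-Z-transformed coefficients (raw-scale comparison is available;
Z-transformed is the default since variance stabilization is the
standard convention for comparing correlation samples), and a Wilcoxon
rank-sum test for distances.  Session-level trends of between-subject
distances are tested with Kendall's coefficient of concordance over
subject pairs × sessions (tie-corrected, chi-square approximation) plus
Bonferroni-corrected pairwise Wilcoxon signed-rank tests.

Subjects missing a session are dropped pairwise with a warning, never
imputed.

## Person identification

`ErrorMapClassifier` is a deliberately small convolutional network that
treats a map as a two-channel 5 × 20 image:

    input (2×5×20) → conv 3×3, 13 filters, valid padding → batch norm
    → ReLU → dropout → fully connected → softmax

trained with cross-entropy under stochastic gradient descent with
momentum.  Fixed task choices: kernel 3, 13 filters, initial learning
rate 0.01, per-epoch shuffling, 350 epochs by default (250–500 is the
sensible range for training sets of this size).  Choices the task does
not pin down are set to the common defaults of image-classifier
toolboxes and are all configurable: dropout 0.5, momentum 0.9, Glorot
uniform initialization, batch normalization with ε = 1e-5 and running
statistics for inference, batch size min(128, N).  One integer seed
drives initialization, shuffling and dropout, making training
bit-reproducible.

The network is implemented directly in numpy (im2col convolution,
standard batch-norm backward pass); at this scale (≈18k parameters,
tens of training maps) a full deep-learning framework adds nothing.

`identification_protocol` wraps any train/test session split — e.g.
sessions (1, 2) → 3, 1 → 2, (1, 2, 3) → 4 — training on every subject's
maps from the training sessions and identifying each subject from their
single held-out map.  Chance is 1/n subjects.

## Trajectory matching

Templates are x = αy + β·sin(πy), y ∈ [0, 1] ≙ 211 mm of depth; α sets
the movement direction (x(1) = α), |β| the curvature.  The default
formal set holds 15 templates on the regular grid
α ∈ {−1, −0.5, 0, 0.5, 1} × β ∈ {−0.9, −0.05, 0.8}; only the ranges and
the count are prescribed by the task, so the regular grid is a
documented stand-in and fully configurable.  The familiarization pair
(0, 0.1) is excluded.

Validity rules: mean speed (path length / duration) ≥ 165 mm/s, no
backward depth step, no movement before the go cue (t < 0).

The motor-error score interpolates the trace's x linearly at the 30
depth cut points y = k/30, k = 1..30 (endpoint included; the start,
where all curves coincide, excluded — the only reading that gives a
well-defined 30-term sum), and returns

    score = sqrt( Σ_k (x_k − x_k,template)² )   [cm]

— the *root-sum-square*, with no division by 30.  The unnormalized form
is kept deliberately: it is the convention this analysis uses and is
consistent with motor errors of ~2 cm magnitude for mm-scale deviation
profiles; `normalized=True` gives the conventional RMS.  Useful closed
forms: a constant offset of d cm scores d·√30; an 0.1-amplitude
curvature offset against a straight template scores 2.11·√15 cm
(Σ sin²(πk/30) = 15).

Endpoint error is the absolute x-deviation at y = 1 (signed vs absolute
is not prescribed; absolute is the default, and the endpoint is immune
to β since sin(π) = 0).

Trajectory-specific localization errors select, on each grid row, the
two column-targets whose x-positions laterally sandwich the template at
that row's depth (ten targets), or only the two far-row targets
bracketing the endpoint.  A template that exits the grid laterally is
clamped to the two nearest columns on that side.

The motor-vs-localization analyses are (i) an across-subject Pearson
correlation of mean motor error with mean localization error (Spearman
when a Shapiro pre-check rejects normality), and (ii) a least-squares
regression of per-trajectory motor error on per-trajectory localization
error with dummy-coded per-subject intercepts and a common slope
(df = N − n_subjects − 1).  Subject identity is treated as a fixed
dummy-coded factor, which is the construction the task describes.

## The synthetic cohort generator

The generator produces cohorts whose *statistical structure* matches
what the analyses assume; it does not model recalibration, sleep
consolidation or biomechanics, and it makes no claim to reproduce any
real cohort's exact numbers.

A subject's measured map in session s is

    map = λ_s · (B + F_i) + ε,   ε ~ N(0, noise_sd²) i.i.d. per target/component

- **B, group bias field** — rightward x-error growing linearly with the
  target's distance from the left shoulder (placed at x = −180 mm,
  y = 0), slope 0.037 mm error per mm distance, magnitude ×1.3 in the
  far rows.  This reproduces the qualitative group-level pattern:
  rightward errors, larger away from the shoulder and in the far
  region.
- **F_i, idiosyncratic field** — per-subject white noise smoothed with
  a Gaussian kernel of correlation length 60 mm over physical target
  distances, scaled so the *expected* RMS vector magnitude is
  `idio_scale` (default 18 mm).  Scaling in expectation (not per
  realization) lets subjects genuinely differ in field strength, which
  the coupling analyses need.  Any smooth seedable field family would
  do; this one has two interpretable knobs (scale, smoothness).
- **λ_s, learning factors** — default (1.00, 0.95, 0.78): accuracy
  improves mainly on the second day, and the session-3 systematic error
  is 78% of session 1 (a ~22% reduction).  Measurement noise is *not*
  scaled by λ_s — practice shrinks the systematic misperception, not
  the trial-to-trial measurement scatter — so at the default noise
  level the observed magnitude reduction is attenuated below 22%;
  the learning-recovery analyses therefore use a low-noise
  configuration (noise_sd = 1 mm) when estimating the factors.
- **noise_sd** — default 16 mm per component.

Calibration: the defaults were chosen (once, by Monte-Carlo over the
generator) to put a 26-subject cohort at a session-1 mean error of
≈3.0 cm, within-subject map correlations ≈0.45 and between-subject
correlations ≈0.15–0.16 — the regime in which idiosyncrasy is present
but far from trivial.  One consequence worth knowing: with this
idiosyncratic-to-bias ratio, far > near holds essentially always at the
cohort level but only for roughly 80% of individual subjects, because a
subject's own field can locally override the shared far-region gain.

Trajectory trials: each of the 15 templates appears twice in a row in a
random per-subject order (30 trials); traces are sampled at 130 Hz with
constant depth speed over 1.2 s (275 mm movements ≈ 229 mm/s, safely
above the 165 mm/s validity floor; richer speed profiles are out of
scope).  The x-deviation from the template is a smooth random profile
(random mix of a linear ramp and the first three sine harmonics,
vanishing at the start) with RMS amplitude

    amp = skill_i · (b0 + b1·|β|) + coupling · local_field_magnitude

with b0 = 3 mm, b1 = 2 mm (giving mean motor scores ≈ 2.3 cm, the
right order of magnitude for this task), skill_i lognormal with
σ_log = 0.2, and coupling = 0 by default — so the no-correlation null
between localization and motor error is *true* under the default
configuration, and type-I calibration of the correlation test can be
checked directly.  Setting `coupling > 0` injects a true dependence via
the subject's field magnitude near each trajectory.

Determinism: all streams derive from seed sequences keyed by
(seed, subject, substream), so a config is bit-reproducible and adding
subjects never perturbs existing ones.

What the generator does **not** emulate: target-order effects,
trial-history dependence, non-Gaussian or spatially correlated
measurement noise, fatigue, hand-dominance asymmetries, or realistic
movement kinematics (speed profiles, submovements).  Passing recovery
tests on these cohorts therefore demonstrates that the analysis chain
measures what it claims under its own assumptions — not that any
particular real cohort satisfies them.

## Problem sizes and numerical choices

The shipped analyses use a 26-subject, 3-session cohort; recovery
studies use 100 replicate cohorts (learning, chance identification),
20 seeds (identification accuracy), and 100–200 cohorts (type-I
calibration) — sizes at which the Monte-Carlo error of each check is
comfortably below its decision margin.

- Binomial criticals use exact tail sums; a tail that cannot attain α
  (tiny n) returns a sentinel (`None`) rather than a misleading count.
- Pearson correlations on zero-variance maps raise; they are never
  silently NaN.
- Cut-point interpolation is linear in y; validity filtering guarantees
  monotone depth, so the interpolation is well-posed.  With 130 Hz
  sampling of an analytic curve the interpolation residual is ~2·10⁻³
  cm, the floor for "exact template reproduction" claims.
- The subject-dummy regression inverts the normal equations directly
  (the designs here are tiny); a rank check rejects collinear designs.

## Known limitations

- The CNN is CPU-only and full-batch at typical sizes; it is not meant
  for maps larger than a few thousand pixels.
- `map_distance` follows the scaled-norm rule; values are therefore
  √100 times smaller than a true per-target mean distance would be.
- The 15-template set is a stand-in grid over the prescribed ranges;
  analyses that depend on the exact template geometry should pass their
  own set.
- Binomial critical counts assume exchangeable subjects; no
  continuity-corrected or mid-p variant is provided.
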