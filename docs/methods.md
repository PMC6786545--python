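# Methods

## Problem setting

A panel of annotators outlines an anatomical structure on each of a set of
2D images by placing ordered points; a second, smaller panel of experts
does the same.  The questions the package answers are: how accurate is
each annotator against the expert consensus; how accurate is the pooled
(majority-vote) panel consensus; how does that compare with the experts'
own internal agreement; and how do behavioural covariates (throughput,
outline detail, age) relate to performance.

## Rasterization

An outline is an implicitly closed polygon in continuous image
coordinates.  Pixel (row r, col c) has its center at (x, y) =
(c + 0.5, r + 0.5); a pixel belongs to the segment iff its center is
strictly inside the polygon under the even-odd rule.  Ties — centers
exactly on an edge — are resolved half-open in both axes: an edge counts
for a scanline only when min(y) ≤ y_scan < max(y), and a crossing at x
claims the pixel columns with center strictly less than x.  Consequences:

* two polygons sharing an edge tile the grid with no double-covered and
  no orphaned pixels;
* a center on the boundary belongs to at most one side deterministically
  (e.g. the unit right triangle covering half of a single pixel yields an
  empty mask, because the center sits on the hypotenuse);
* results are invariant under integer translation.

Self-intersecting outlines (annotators do produce them) are filled under
the same even-odd semantics rather than rejected.  Zero-area (collinear)
outlines rasterize to an empty mask with a warning; a record whose every
region is degenerate is an error.  Multiple regions in one record are
merged by set union, so annotator-drawn holes are not representable — a
deliberate non-goal.  All geometry is in pixel units; physical pixel
spacing is metadata only.

The implementation is a vectorized scanline fill; the test suite checks
it pixel-for-pixel against an independent per-point crossing-number
oracle on hundreds of random simple polygons (including
vertex-on-pixel-center configurations forced by integer coordinates), and
against `matplotlib.path` away from boundary ties.

## Consensus

The consensus map of an image is the per-pixel fraction of annotators
whose mask includes the pixel; the denominator is the number of
annotators *who segmented that image* (panels cover random subsets, so a
roster-wide denominator would make consensus unattainable on sparsely
covered images).  The consensus segmentation keeps pixels with fraction
strictly greater than a threshold t ∈ (0, 1); t = 0.5 is the majority
vote (with 3 experts this requires ≥ 2 votes; with an even panel an exact
tie is excluded).  Thresholding compares integer vote counts, so floating
point cannot flip a pixel at an exactly attained threshold.  Nesting is
immediate: the 0.75-segment ⊆ 0.5-segment ⊆ 0.25-segment.

Repeat segmentations of an image by the same annotator count toward
throughput but are excluded from accuracy analyses, keeping the
earliest-session record.  Images covered by fewer than a configurable
minimum of annotators (default 3) are flagged but still processed.
STAPLE-style weighted fusion is out of scope: the method evaluated here
is the plain majority vote.

## Scoring

Dice(A, B) = 2|A∩B| / (|A|+|B|).  Conventions: Dice(∅, ∅) = 1,
Dice(∅, non-empty) = 0 — real outlines never produce empty masks, but the
convention keeps degenerate synthetic cases defined (its use triggers a
warning).  Scores are assembled into tables of (image, subject,
reference, dice) and summarized per image and per annotator with n,
median, mean, SD, min, max.  When a citizen is scored against the
*citizen* consensus their own mask is included in that consensus
(leave-self-out is available but off by default); the headline comparison
is against the *expert* consensus, where the issue does not arise.
Summary-of-summaries statistics use per-image medians of individuals,
then mean/SD of those medians across images.

## Behaviour statistics

* Throughput: two-sided Mann-Whitney U between per-annotator image counts
  of two sessions.  U follows the rank-sum convention
  U = R_a − n_a(n_a+1)/2 with midranks for ties.  For samples of at most
  8 each, the p-value enumerates all C(n_a+n_b, n_a) group assignments
  (ties handled exactly); larger samples use the tie- and
  continuity-corrected normal approximation.  The exact branch is checked
  against an independent pair-counting enumeration for all sample sizes
  up to 6×6; sessions lost to data failure are represented as absent, not
  zero.  One-sided variants and alternative tie conventions are not
  exposed: two-sided midrank testing is the package's single documented
  convention.
* Outline detail vs volume: Pearson r between each annotator's mean
  points per image and total images analysed, two-sided t-test on n − 2
  degrees of freedom.
* Age vs accuracy: Pearson r between age and the annotator's median Dice
  against the reference consensus, plus the least-squares slope rescaled
  to Dice per decade.  Annotators without age are excluded with a
  warning; zero variance in either variable is an error, not a NaN.

## The synthetic study

Because no annotation data ship with the package, a simulator generates
studies with the structure the pipeline expects.  Defaults describe a
150-image study with 29 citizens and 3 experts.

**Ground truth.**  Each image holds one vertebra-like shape on a
128 × 128 px grid (0.49 mm/px carried as metadata): a *body* — an ellipse
(mean radius uniform in 14–23 % of the grid side, i.e. ≈ 18–30 px; aspect
0.72–0.98; random orientation) modulated by low-order harmonics
(k = 2..4, amplitudes ~N(0, 0.03) clipped at ±0.08), star-convex about
its center by construction — plus a thin tapered posterior *process*
(half-width 2.2–3.6 px, length 0.55–0.95 body radii).  The thin structure
is where agreement degrades fastest, reproducing the round-vs-thin
contrast seen in real inter-rater data; the grid size is a desk-scale
choice that keeps the noise-to-size regime (boundary jitter of 1–3 px on
a ~22 px-radius body) where individual Dice ≈ 0.9.

**Annotators.**  A model is (sigma, bias, n_points, gross_error_rate): an
outline samples n_points positions arc-length-uniformly along the true
boundary (random phase) and displaces each by bias + N(0, sigma) pixels —
radially from the center for the body, which preserves simplicity of the
polygon; along the outward normal for the thin process.  With probability
gross_error_rate the outline is replaced by a shrunken (×0.55) body
outline displaced by 0.4–0.8 body radii.  Defaults: citizens sigma ~
lognormal(median 1.5 px, log-SD 0.45) clipped to [0.4, 4.5], bias ~
N(0, 0.8 px), n_points uniform 36–130, gross errors 2 %; experts sigma
uniform 0.5–0.9 px, bias ~ N(0, 0.2 px), no gross errors.  Under these
defaults the emergent statistics land where a real citizen-vs-expert
study sits: per-image median individual Dice ≈ 0.93, citizen consensus
vs expert consensus ≈ 0.97, inter-expert pairwise ≈ 0.97.

**Design.**  Experts segment all images.  Each citizen's workload is
drawn from a normal (mean 85, SD 43) truncated to [1, n_images] and
rounded; assigned images are a uniform random subset, split across 3
sessions.  No truncated normal on [1, 150] can have *empirical* mean 85
and SD 43 simultaneously (the supremum SD at mean 85 is ≈ 42.4, the
exponential-tilt limit), so the configured values parameterize the parent
normal and the sampler is tested against the exact truncated moments.
Ages are uniform on 18–73 years; an optional `age_sigma_slope` plants an
age→noise effect (default 0) so the age regression has a recoverable
truth.  All randomness derives from one top-level seed through named
substreams (shapes, assignment, ages, per-outline), making every stage
independently reproducible; equal seeds give byte-identical output
tables.

**What the simulator does not emulate.**  MR image intensities (there are
no images, only geometry); learning effects across sessions; correlated
errors between annotators (each is independent given the truth);
anatomical pathology or multi-structure scenes.  Passing tests therefore
demonstrate that the *pipeline arithmetic* is right and that majority
voting behaves as theory predicts under independent noise — not that any
particular human panel reaches any particular accuracy.

**Parameter recovery.**  Because radial noise leaves the polar angle
fixed, the signed radial deviation of each body vertex from the true
boundary equals the planted perturbation exactly; the per-annotator SD
and mean of pooled deviations recover sigma and bias (within ~15 %
relative at ≥ 30 outlines; the estimator assumes no gross errors).

## Numerical and design choices

* Scanline fill toggles column parity with integer indices from
  `ceil(x − 0.5)`, so threshold and tie behaviour is exact, not
  epsilon-based; consensus thresholding likewise compares integer counts.
* Dice and consensus are computed on boolean arrays; no smoothing,
  anti-aliasing or sub-pixel weighting anywhere (a non-goal).
* The Mann-Whitney exact/asymptotic switch is at n = 8 per sample: full
  enumeration is C(16, 8) = 12 870 splits at worst, instantly exhaustive,
  while the normal approximation is standard above that.
* Pipeline outputs are deterministic functions of the inputs; the seed in
  the run configuration exists for provenance of simulated inputs.
* Tables are CSV; masks are 8-bit PNG (0/255); consensus maps are stored
  as integer vote-count lattices with a JSON sidecar so they round-trip
  exactly.

## Known limitations

* Polygons with holes cannot be represented (union-of-regions semantics).
* The consensus is an unweighted vote; systematically biased annotators
  shift it (by design — that is the method under evaluation).
* `estimate_annotator_noise` is specific to the simulator's radial noise
  model; it is a validation tool, not a general boundary-error estimator.
* The original human-study data are not deposited, so the package's
  full-scale numbers characterize the simulator's default conditions, not
  the human panel.
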