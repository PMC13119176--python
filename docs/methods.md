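# Methods

## The problem and the model of it

`calmaug` treats data augmentation for long-tailed detection as
*distribution reconstruction*: the empirical training distribution is
deficient along three axes — class frequency, object-center position, and
object scale — and each pipeline stage is an explicit operator on one or
more of those axes. The package never trains a detector; its contract is a
dataset-in → dataset-out transformation whose effect is measured by the
distribution diagnostics it also provides.

### Per-class floor targets

Augmentation quotas are a floor scheme: `pastes_i = max(0, T_i − N_i)` for
per-class targets `T` (scalar or vector, default 54). A floor directly
produces a guaranteed post-augmentation minimum count, which is the
quantity that controls whether a class participates in gradient updates
often enough to be learned. Inverse-frequency reweighting was the obvious
alternative; it was rejected because it has no interpretable guarantee on
the minimum and because a floor composes cleanly with screening losses
(see resampling below). No single scalar target can simultaneously set an
observed post-augmentation minimum *and* maximum; when both matter,
per-class vectors are the configuration surface.

### Placement and scale laws

Paste placement is uniform over the set of admissible centers (scaled box
fully inside the frame, IoU with every existing box ≤ `max_overlap_iou`,
default 0.1), realized by rejection sampling with a 50-draw budget. Uniform
— not center-biased — placement is the debiasing mechanism: it puts mass in
the edge and corner cells where field photos have almost none. Scale jitter
is log-uniform over ×[0.5, 2.0] applied to the donor's native normalized
scale, clipped to keep boxes inside (0, 1]; log-uniform makes halving and
doubling equally likely.

Donor crops carry a soft alpha. The default mask is a rectangle with a
raised-cosine border ramp (feather width 8 % of the smaller crop side):
hard-edged pastes leave seam artifacts that a detector can exploit as a
synthetic-sample cue. A binary mask mode exists for tests that need exact
pixel locality, and ground-truth soft masks are used verbatim when the
caller has them (the synthetic generator supplies them). The new
annotation's box is the bounding rectangle of alpha > 0.5, so box geometry
follows the visible object, not the padded crop.

### Environment stage

Order is fixed: luminance → weather → occlusion, so the visible-fraction
accounting done by the occlusion step describes the final raster. Every
effect at zero intensity or zero probability is a bit-exact no-op — this
invariant is what makes "effect off" composable and testable. Weather
phenomena are fog (alpha blend toward a 220-gray veil modulated by smooth
spatial noise; strictly contrast-reducing), rain (oriented bright streaks)
and Gaussian blur with σ = 3·intensity pixels, chosen so intensities
compose in quadrature like Gaussian widths. Visible fractions are measured
on the occluder raster rather than analytically so arbitrary occluder
shapes stay consistent with the metadata. Defaults (gain ∈ [0.4, 1.6], at
most 50 % of a pasted box occludable) are deliberately harsh; all are
config fields.

### Screening as accept–reject sampling

The teacher is an interface (`predict(sample) → detections`); the package
ships only the oracle test double and adapters are the caller's concern.
Matching between pasted boxes and detections is one-to-one greedy by
descending IoU — the simplest scheme whose acceptance decision is monotone
in both thresholds. Default thresholds are τ = 0.25 (confidence) and
θ = 0.5 (IoU): θ = 0.5 is the conventional localization-agreement cut in
detection metrics, and τ = 0.25 a typical inference-time confidence floor;
both are mandatory config fields rather than constants. Rejection is
whole-sample by default (one bad paste invalidates the composite) with a
per-box salvage mode left out of scope; occlusion-based rejection
(`min_visible_fraction`, default 0.5, aligned with the occlusion cap) lives
here because "too occluded" is a quality judgment, not a rendering one.
Rejected samples are dropped by default; `rejected_mode="resample"`
re-plans residual deficits for up to 10 rounds, pasting one box per
replacement sample so a whole-sample rejection costs exactly one paste and
residuals shrink geometrically.

Original (pre-existing) boxes are never screened: they are real data, and
rejecting them would delete ground truth.

### Diagnostics

All statistics use instance (box) counts, not image counts. The imbalance
ratio excludes zero-count classes from the minimum (logged) instead of
returning infinity. Log dispersion is the *population* standard deviation
of natural-log counts; the base is configurable since only ratios of this
statistic are base-dependent, and it is invariant under global count
rescaling — the property that makes it comparable across dataset volumes.
Histograms use half-open bins [l, u) with the final bin closed and
interior-edge values going up; an all-zero grid is the sentinel for a
dataset with no boxes.

### Splitting

Stratified 8:1:1 splitting assigns each image the stratum of its majority
class (ties → lowest class index; label-free images form their own
stratum) and apportions within strata by largest remainder, which bounds
the per-stratum deviation from the ratios at one image. Majority-class
stratification is a design choice: multi-label images have no canonical
stratum, and the majority class is the one whose balance the image most
affects.

## The synthetic generator

`generate_dataset` emulates the statistical structure the pipeline
targets, not the appearance of any real dataset: a vein-textured leaf
ellipse over smoothed soil-toned noise, lesions as speckled, dark-rimmed
elliptical blobs with golden-ratio-spaced hues so classes are separable.
Requested per-class counts are realized *exactly* (instances that fail
placement in one frame spill into the next). Centers follow the mixture
law (1−b)·Uniform + b·truncated-Normal(0.5, 0.12) with b = 0.6 by default;
scales are uniform over √(w·h) ∈ [0.08, 0.22]; ground-truth overlap is
capped at IoU 0.1 so the oracle teacher's matching is unambiguous.

The default count vector (30 classes, 755 down to 2, total 8654) is a
two-regime exponential decay frozen in `PLANTDOC_LIKE_COUNTS`. It was
chosen once to reproduce the study conditions of a severely imbalanced
30-class field dataset: imbalance ratio 377.5, 17/30 classes with ≥ 200
instances (56.7 % coverage), and log-count dispersion ≈ 1.20. With those
constraints and a smooth decay the head classes hold 84 % of instances; a
real dataset's head share can differ a few points since its tail need not
decay smoothly.

What passing tests on these fixtures shows — and does not. They verify the
*mechanics*: exact count realization, placement laws, blending locality,
effect identities, screening logic, determinism, and that the pipeline's
distributional guarantees (floor, IR decrease, coverage dominance) hold
end-to-end. They cannot show that augmented samples are photometrically
plausible for real crops, that a real teacher's acceptance behaves like the
oracle's, or that a detector trained on the output improves — those require
real imagery and training runs, which are out of scope here.

The oracle teacher reads the sample's own ground truth and re-emits each
box with probability p, optional confidence jitter and pixel-level box
jitter; with p = 1 and zero noise its predictions equal ground truth with
confidence 1 (the invariant the perfect-teacher tests rely on), and p is
directly the expected acceptance rate for single-paste samples — the
calibration the screening tests check binomially.

## Numerical and reproducibility choices

* Images are uint8 RGB; every float operation rounds with `rint` then
  clips, so repeated identity-parameter application is stable.
* Pixel space is top-left origin, half-open boxes after denormalization;
  label files print 6 decimals, making read→write→read a fixed point.
* One global seed fans out per stage as `seed XOR crc32(stage_name)`
  (mod 2³¹−1), so adding a stage never reshuffles another stage's stream.
* Degenerate inputs: sub-2-pixel crops are skipped with a warning; empty
  donor classes with a positive deficit are a hard, named error; placement
  exhaustion retries on a new background with a global budget of 10× the
  total deficit before failing.
* Problem sizes in the shipped checks: the full-scale fixture (8654
  instances, ~1950 images at 256 px) for the end-to-end run, 10⁴ draws for
  uniformity checks against 3σ multinomial bounds, 10³ samples for the
  screening calibration (±0.03), 2×10² for threshold monotonicity —
  chosen as the smallest sizes at which the statistical bounds are
  meaningfully tight.

## Known limitations

* Box-shaped (feathered-rectangle) pastes by default; no learned or
  saliency-based lesion segmentation. Mask-shaped pastes happen only when
  ground-truth masks are supplied.
* No host-plant compatibility model at paste time — a lesion may land on
  soil or the wrong species; screening, not paste-time rules, is the
  intended guard, and with the oracle teacher that guard is permissive.
* Whole-image geometric augmentation (flips, rotations, mosaics) is out of
  scope by design; the mechanism here is object-level recomposition.
* Kept augmented images retain their background's original boxes as
  labeled instances, so head-class counts grow slightly too; the
  post-augmentation imbalance ratio is marginally above `max N / T`.
* The per-class count vectors of real datasets are inputs, not outputs:
  statistics like the post-augmentation log dispersion of a specific real
  corpus cannot be reproduced from this package alone.
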