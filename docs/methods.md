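# Methods

This note documents the models, numerical choices and limitations behind
`facesym`: what each pipeline stage computes, why the defaults are what
they are, what the synthetic-data generator does and does not emulate,
and therefore what the test suite does and does not demonstrate about
real clinical recordings.

## Coordinate and laterality conventions

All coordinates are image-plane pixels with the origin at the top-left
corner, x rightward and y **downward**; frame indices are 0-based.
"Left" means image-left throughout. The eye centroids carry explicit
`eyeL`/`eyeR` labels in the trajectory format; facial laterality of a
marker pair is derived from them: the "left" member of a pair is the one
lying (in the median over frames) on the same side of the symmetry axis
as the left-eye centroid. For an upright face this coincides with simply
ordering the pair by image x, but unlike the raw-x rule it is covariant
with rigid motion of the whole scene — the Ratio feature therefore does
not flip to its reciprocal under large head roll. The orientation used
(`left_over_right` by default) and the resolved left/right marker ids
are recorded in every Ratio output's metadata.

## Preprocessing

Two cleaning steps target eye-detection failures, in this order:

1. **Single-frame gap interpolation.** An invalid frame whose immediate
   neighbors are both valid is filled with their coordinate-wise
   midpoint. Longer gaps are left invalid and simply drop out of all
   downstream per-frame computations; inventing multi-frame data would
   bias the derivative descriptors.
2. **IPD-relative jump filtering.** A frame is an artifact when the
   Euclidean step from the previous frame exceeds
   `jump_threshold_fraction` (default 0.10) times that frame's
   interocular distance, making the criterion independent of image
   resolution and face scale. The offending coordinate is replaced by
   the mean of its two neighboring frames. The pass runs left to right
   and measures each step against the *working* (already corrected)
   previous frame: once an isolated jump is fixed, trajectory continuity
   is restored and the return step to the clean path is not itself
   flagged, so the set of replaced frames equals the set of true
   isolated artifacts. The threshold always uses the current frame's
   pre-replacement IPD; a degenerate IPD (coincident detections) falls
   back to the recording median. First/last frames cannot be replaced
   (no two neighbors) and only produce a warning.

The jump filter is applied to eye centroids; marker tracks can opt in
via `filter_marker_tracks` but are left alone by default, since marker
detection quality control belongs to the upstream tracking stage.

## Symmetry axis

The per-frame axis is the perpendicular bisector of the interocular
segment: direction `(a, b)` is the normalized interocular vector and `c`
places the line through the midpoint. Coefficients are unit-normalized
with a sign convention (a ≥ 0; b > 0 when a = 0) so each geometric line
has exactly one representation and axes are bit-stable across frames and
runs. The axis is a geometric construct, not an anatomical midline; it
is reported unchanged under arbitrary head roll, and no verticality
constraint is imposed. Frames with missing or coincident eye centroids
are omitted and logged.

## Features

For the exercise's homologous pair (00/01 for eyebrow raising, 10/11 for
smiling; overridable per config):

* `VertDist(t) = |y_i(t) − y_j(t)|` uses raw image-frame y, not
  axis-aligned coordinates — vertical displacement is the primary
  discriminative quantity, and the simplicity is deliberate. It is
  translation-invariant and scales linearly with image scale, but *not*
  roll-invariant: head roll leaks the pair's horizontal separation into
  VertDist at a rate of separation × sin(roll).
* `Ratio(t) = d_L(t)/d_R(t)` with the point-line distances of the two
  members; it is invariant under rigid motion and global scale. Frames
  where the denominator marker lies within `ratio_degeneracy_floor`
  (1e-6 px) of the axis are dropped with a warning instead of producing
  infinities; this cannot occur for realistic marker placements.

Both companion distance series (`dist_left`, `dist_right`) are exported
for inspection.

## Descriptors

Each feature series of each recording is normalized with a robust
z-score, `(x − median) / (mad_scale × MAD)`, computed per feature per
recording so that descriptor values are comparable across subjects and
insensitive to outliers and to absolute motion scale. `mad_scale`
defaults to 1.4826 (normal consistency with the SD); raw-MAD mode is a
config switch. A zero MAD falls back to a normal-consistent IQR scale
(IQR/1.349); a fully constant series normalizes to all zeros with a
warning — degenerate inputs yield zero descriptors, never NaN.

Dispersion of the normalized series gives STD (sample, n−1), MAD
(scaled as above) and IQR (linear-interpolation quantiles, config
pinned). The first derivative is the forward difference within
contiguous frame runs — never across gaps — in per-frame units by
default (`per_second` multiplies by fps; with fps fixed across a study
the choice is a pure rescaling that cancels in group comparisons).
Dispersion of the derivative gives dSTD, dMAD, dIQR. The default order
is normalize-then-differentiate; the reverse order (differentiate, then
robustly normalize the derivative) is available for sensitivity
analysis via `normalize_before_derivative`.

One structural consequence worth knowing: the MAD of a MAD-normalized
series is identically 1 (up to floating rounding) in every recording, so
the `*_MAD` descriptors of the normalized series carry no between-subject
information. The statistics stage detects such structurally constant
descriptors (relative tolerance 1e-9) and reports them without a test
(NaN t/p/g) instead of testing numerical noise.

## Statistics

Per descriptor, the S and AS groups are compared with Welch's
unequal-variance *t*-test (p two-sided from Student's t at the
Welch–Satterthwaite df) — appropriate for the unequal group sizes — and
bias-corrected Hedges' g with the pooled (n_A + n_B − 2)-df SD and
correction J = 1 − 3/(4·df − 1). Both t and g are computed as AS − S, so
descriptors higher in the symmetric group are negative. Shapiro–Wilk
(per group) and Levene's test are advisory only; Welch is used
regardless. Levene uses median centering (Brown–Forsythe variant), the
robust default of the underlying library. No multiple-testing
correction is applied by default, matching the per-descriptor p < 0.05
convention; a Holm step-down option exists behind a config flag.

ROC analysis treats S as the positive class by default
(config-switchable); the curve is the empirical ROC over all distinct
thresholds, AUC is the trapezoid area (equal to the Mann–Whitney
concordance probability with half-credit for ties), and the operating
point maximizes the Youden index with ties broken toward the lower
threshold. Descriptors are ranked both by |g| and by AUC; AUC ties —
routine under perfect separation in small cohorts — break toward the
larger |g|, then lexicographically, so rankings are deterministic.
`max(AUC, 1 − AUC)` is reported as orientation-free separability.

Fleiss' kappa is computed from the category-count matrix of the rater
panel; a panel unanimous in a single category has expected agreement 1
and raises an explicit error rather than returning 0/0. Majority
labeling requires a strict majority and raises on ties.

## Synthetic cohorts

The generator stands in for private clinical videos, so its defaults
encode the acquisition conditions being emulated: 50 fps, 20 s per
exercise, interocular distance ~120 px, analysis markers ±40 px lateral
of the midline, 17 markers total (the 13 non-analysis markers are placed
statically on the face), and around 8 exercise repetitions per
recording.

Motion model, per recording:

* Eyes and the exercise pair start mirror-symmetric about a vertical
  midline. Each repetition displaces the pair along the exercise axis —
  straight up for eyebrow raising, obliquely outward-and-up for smiling
  — with a raised-cosine pulse occupying 60% of its repetition period,
  leaving rest intervals as in real exercise execution. Pulse amplitudes
  vary per repetition (uniform ±30%, same factor on both sides, so
  symmetry is unaffected): no one repeats a movement identically.
* Asymmetry uses the two mechanisms that make real executions look
  asymmetric: the right side's amplitude is scaled by ρ ∈ (0, 1] and/or
  delayed by a phase lag. Ground truth is S iff ρ = 1 and lag = 0.
* Rigid head motion is a slow (~0.1 Hz) bounded wobble in translation
  and roll whose peak velocities are the configured rates — a seated
  participant instructed to hold a neutral pose sways, but does not
  drift monotonically out of frame.
* Non-rigid realism: each track carries smooth, temporally correlated
  micro-motion (low-pass-filtered Gaussian noise, SD 1 px, timescale
  0.5 s) modeling skin/muscle-tone fluctuation and slow detection
  drift, plus white Gaussian detection jitter (SD 1 px). Without the
  correlated component, symmetric recordings would be implausibly
  "dead" — pure white noise around a constant — and trivially
  separable from any structured signal by distribution-shape statistics
  alone.
* Detection failures: isolated single-frame dropouts and isolated
  eye-centroid jumps (default magnitude 15% of IPD) at configurable
  per-frame rates, each drawn from its own RNG stream so toggling
  artifacts never changes the motion realization. Injected events are
  recorded as ground truth for filter validation.

Cohorts derive per-subject seeds deterministically from one cohort seed
and add mild between-subject variation to amplitude, baseline geometry
(IPD, marker offsets), noise levels, repetition count and head-motion
rates. The group-defining parameters ρ and lag are never jittered, so
planted effects and null configurations are exactly as specified.

### What the simulator does not emulate

No out-of-plane head motion (nodding/yaw foreshortening), no
biomechanical coupling between markers, no photometric effects, no
marker occlusion beyond single-frame dropouts, and — importantly — no
symmetric-but-structured facial activity beyond the micro-motion model.
Real symmetric executions are richer, which is why the synthetic
separations are far cleaner than anything observed clinically: planted
ρ = 0.5 cohorts yield |g| in the 3–8 range and AUCs near 1.0, whereas
clinically realistic effects are an order of magnitude smaller. Passing
the planted-effect tests demonstrates that the pipeline recovers a known
asymmetry signal with correct direction and ranking — not that these
effect sizes transfer to patients. A further geometric consequence of
the motion model: a purely vertical exercise (eyebrow raising) does not
modulate marker-axis distances, so its Ratio descriptors carry little
signal in simulation; the oblique smiling motion modulates both features
and is the configuration used for effect-recovery validation.

## Validation problem sizes

The heavy simulation checks run at cohort sizes of 50 S / 20 AS with
full-length (20 s, 1000-frame) recordings: 200 replicates for null
calibration (type-I error inside the exact binomial 95% interval around
α = 0.05; per-descriptor mean AUC within 0.5 ± 0.1) and 100 replicates
for planted-effect recovery. Geometry is checked on 1000 random
point/line instances against a brute-force coarse-to-fine minimization
over ~1.2 × 10⁵ sampled line points, and the statistical battery against
independent reference implementations on 500 random instances per
statistic. These sizes keep the whole suite to a few minutes while
leaving the binomial calibration checks adequately powered.

## Known limitations

* 2D only; no 3D head-pose compensation. VertDist degrades gracefully
  under roll but is not invariant to it.
* The symmetry axis depends entirely on eye-centroid quality; systematic
  (bias-like) eye-detection error translates directly into Ratio bias.
* Descriptors assume the robust z-score is meaningful, i.e. series long
  enough (≥ 3 frames, in practice hundreds) and not pathological.
* The statistics stage performs univariate descriptor screening, not
  classification; reported operating points are descriptive.
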