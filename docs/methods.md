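# Methods

This note documents the models, conventions and numerical choices behind
`ofsdn`, in the spirit of a package methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## Conventions

All angles are degrees. Motion directions live on [0, 360) with 0° =
rightward, 90° = up, counterclockwise positive — chosen so that the
classification bands (left DN1 120–200°, right DN1 340–60°, DN2 220–320°)
read literally. Times are seconds from trial start; stimulus steps are
half-open intervals [onset, onset + duration); frame indices are 0-based.
The fly-centred spatial frame is x right, y forward, z up.

## Circular statistics

- **Circular mean / resultant.** Argument and normalised modulus of the
  (optionally weighted) complex sum Σw·e^{iθ}. A resultant below 1e−12 marks
  the mean undefined (NaN) rather than returning an arbitrary angle.
- **Circular median.** The direction minimising the mean circular absolute
  deviation d(m) = mean(π − |π − |θᵢ − m||). Candidates are the sample
  angles; for even n the two central minimisers are averaged along their
  shorter arc; ties (including antipodal pairs) break toward the circular
  mean. A property test checks agreement with an exhaustive 0.01° grid
  minimiser; because d has slope at most 1, the achieved deviation can
  differ from the grid minimum by at most one grid step.
- **Dispersion.** Circular variance 1 − R (unitless) and angular deviation
  √(2(1−R)) in degrees are both exposed. The receptive-field exclusion
  threshold of 30° is applied to the angular deviation, the only one of
  the two on a degree scale; the threshold is a parameter so it can be
  re-pointed at raw variance if desired.
- **Cosine (first-harmonic) fit.** For n directions equally spaced over
  360°, the least-squares fit of b + A·cos(θ − φ) has the closed form
  b = mean(r), C = (2/n)·Σ r·e^{iθ}, A = |C|, φ = arg(C); unequal spacing is
  rejected because the closed form is then invalid. A zero-amplitude fit
  flags the phase undefined.
- **Watson–Williams test.** Standard two-sample F with the concentration
  correction 1 + 3/(8κ̂), κ̂ estimated from the pooled within-sample
  resultant by the usual three-regime approximation; p from F(1, N−2).
  When the pooled resultant is below 0.45 the result carries a
  low-concentration warning flag instead of aborting, so pipelines survive
  marginal data.

## Receptive-field mapping

Per location, the local maximum spike frequency above spontaneous and the
cosine fit (LPD = phase, LMS = amplitude) are computed from the mean rates
over repetitions. Local maxima are floored at 0 before map construction —
suppression below spontaneous cannot contribute receptive-field area. The
lattice of local maxima is interpolated tenfold per axis; the kernel is
bilinear (node-preserving) with a bicubic spline behind a flag, since the
original analysis states only the resolution factor. The 50 %-of-maximum
contour is traced by marching squares on a map padded with a sub-level
frame, so contours clipped by the map border close along the border (and
are flagged as clipped); among candidate polygons the one enclosing the
map maximum wins, largest-area first. Width and height are the polygon's
axis-aligned bounding-box extents; the centre is the area centroid.

The receptive-field preferred direction is the circular median of LPDs at
locations with LMS strictly above half the maximum; the LPD angular
deviation of the same set and the set's size feed the exclusion rule
(max LMS < 20 spikes/s, ≤ 4 supra-half locations, deviation > 30°; every
failed criterion is reported). Classification intervals are closed at both
ends; the left/right boundary for DN2 centres sits at azimuth 0 (screen
midline), with azimuth ≥ 0 read as right-hand side. Display transforms
(ventral-side-up 180° rotation with both map axes negated; midline mirror
θ → 180° − θ with azimuth negated) are involutions and preserve LMS values
and the supra-half count exactly.

k-means clustering of neuron features (50 seeded restarts) z-scores each
column and evaluates partitions with a Calinski–Harabasz index computed
from its definition. The preferred direction enters as a plain linear
feature, mirroring common practice; the circular wrap is not special-cased,
which is safe while the four classes sit far from the 0/360 seam of the
z-scored coordinate but is a documented caveat otherwise.

## Neural responses

Spike rates use a centred square-wave filter, width 100 ms, on a uniform
grid of 0.025 ms (the 40 kHz acquisition step); at the series edges the
window is truncated and renormalised by its overlap, keeping a stationary
train unbiased. Windowed means count spikes in [t₀ + skip, t₁] over the
effective duration; the direction-tuning protocol skips the first 100 ms of
each 1-s presentation. Spontaneous rate supports the three protocol windows
(0.8 s mapping, 0.48 s optic-flow, 2 s velocity trials); when less
pre-onset data exist than the window asks for — the velocity trials start
after only a 1-s blank — the available span is used and the result flagged,
a deliberate truncation-with-flag resolution of that protocol conflict.

Velocity response functions take, per step, the mean rate over the final
second; repetitions pool across trials; the per-velocity summary is the
median, minus the across-repetition *mean* response at velocity 0 (the
stationary stimulus). Onset detection computes the window mean m (0.97 s
with a 0.1 s skip for neurons; final-second mean for behaviour) and returns
the first grid point at or above 0.8·m, using ≥ with a relative 1e−9
whisker so exact crossings are not lost to floating-point rounding; a
non-positive m is flagged degenerate. Resolution is one grid step (0.025 ms
neural, 10 ms behavioural).

## Stimulus mathematics

Starfields are uniform random sphere centres (2 cm diameter by default) in
an axis-aligned box. Ego-motion is applied as the inverse scene transform:
positive thrust recedes points along +y, positive sideslip moves the image
leftward, positive lift moves it downward; rotations are rigid rotations by
−ω·dt about roll = y, pitch = x, yaw = z, making positive roll
counterclockwise on screen. Points leaving the box re-enter wrapped on the
opposite face (keeping density stationary); wrapping is a separable step so
rigid-motion invariants can be checked on the unwrapped transform.
Projection is pinhole onto the screen plane at y = distance, with the exact
angular diameter 2·asin(r/D) (indistinguishable from 2·atan at protocol
ranges, but one convention is pinned). The per-frame displacement check
differences viewing directions across one refresh (165 Hz default) over
points visible in both frames — the quantity that caps usable stimulus
velocity. Velocity schedules are uniform seeded permutations of the full
velocity × repetition multiset (not block-randomized); the default rotation
list is the symmetric −200…+200 °/s set, with the historical asymmetric
variant (leading +200) available behind a flag.

## Tethered-flight kinematics

WBA of a wing is the unsigned angle at the anterior thorax point between
the thorax axis (posterior → anterior) and the wing-tip vector: 90° when
perpendicular, 180° when the tip lies on the axis behind the thorax. Head
angle is the signed angle between the two-point head line and the thorax
axis, folded into (−90°, 90°] (a line has no orientation), positive toward
the animal's right in the dorsal view. Leg extensions are Euclidean
distances (foreleg proximal–distal; hindleg knee to lateral mid-abdomen),
averaged over sides, with the right-minus-left hindleg difference; a side
with unusable keypoints is dropped from the average and flagged, and hidden
forelegs are missing values, never zeros.

Quality control runs on the WBA series of each wing:

1. **Tracking artefacts.** The series is smoothed with plain and robust
   local regression of identical span — local quadratic polynomials with
   tricube weights over 0.5 s (51 frames), the robust variant adding five
   bisquare reweighting passes (scale 6 × median absolute residual, with a
   floor so an interpolating fit does not collapse the scale). Frames in any
   run where |plain − robust| / max(|robust|, 1°) exceeds 5 % for more than
   1 s are excluded. The smoothing exists only for error detection; all
   metrics are computed from unsmoothed data. Note a structural property of
   this rule: strictly zero-mean alternating jitter is invisible to it,
   because both smoothers average it away (measured discrepancy ≈ 1.6 % for
   ±30° alternation on a 60° baseline). What it does catch — and what the
   synthetic glitch model therefore emulates — are one-sided excursions,
   the signature of a keypoint snapping to a wrong position.
2. **Flight cessation.** Runs where either wing stays below 40° for at
   least 0.5 s are marked not flying.
3. **Trial exclusion.** Trials with a not-flying fraction strictly above
   50 % are dropped entirely (exactly 50 % is kept); head and leg data
   inherit all WBA exclusions.

Kinematic velocity response functions mirror the neural ones: per-step
means over valid frames in the final second, per-velocity medians across
valid repetitions, stationary-response subtraction per metric.

## Synthetic data

The neuron generator draws Poisson counts at rate
max(0, spontaneous + envelope·LMSmax·cos(θ − LPD)) with a Gaussian spatial
envelope; rates are floored at 0 before sampling, so suppression saturates
at silence. The default mapping lattice is 8 × 6 patch centres 20° apart
(48 overlapping ~38° patches); presentations last 0.36 s with 5 repetitions.
Velocity tuning is a signed Hill sigmoid g(v) = r_max·|v|ⁿ/(|v|ⁿ + v₅₀ⁿ)
(defaults r_max 150 spikes/s, v₅₀ 0.4, n 1.5, anti-preferred suppression
0.3·r_max), on top of a 20 spikes/s spontaneous rate — magnitudes chosen to
look like healthy wide-field neurons, configurable, and labelled synthetic
throughout. Because of the rate floor, the observable stationary-subtracted
tuning is max(0, spont + g(v)) − spont; recovery tests compare against this
observable, not the raw g. Rectification also biases the fitted LPD of a
strongly-driven location slightly away from the generating direction when
the direction grid is not symmetric about it (≈ 2° at amplitude/baseline
4:1); recovery tests therefore measure against the noiseless rectified-fit
phase, the quantity the estimator actually targets.

The flight generator builds keypoints whose derived metrics equal the
template's WBA/head/leg series exactly (machine precision round-trip),
then adds Gaussian noise (1° default), response latency (0.3 s), scheduled
one-sided glitch blocks and sub-40° flight stops. What the generators do
*not* emulate: biophysical spiking dynamics, adaptation, correlated noise
across locations, video artefacts other than keypoint glitches, or sex
differences — so passing recovery tests demonstrates correctness of the
estimators under the assumed statistical structure, not robustness to every
failure mode of real recordings.

## Problem sizes and statistical checks

Recovery checks run at deliberately modest sizes: classification recovery
uses 100 simulated neurons per class (5 repetitions each); velocity-response
recovery uses 9 Poisson repetitions per velocity across 13 velocities;
oracle comparisons use 1000 random samples. The velocity-recovery
comparison is a difference of two estimates (a velocity median minus the
stationary mean), so its standard error combines both terms; a maximum
z-statistic over 13 velocities occasionally exceeds 3 by ordinary sampling
fluctuation, which is expected behaviour of the statistic rather than an
estimator defect.

## Known limitations

- The circular-median tie-break and even-n midpoint rule pin one of several
  defensible definitions; toolboxes differ in degenerate cases.
- The 5 % artefact-rule reference is relative to the robust-smoothed value
  with a 1° floor; an absolute-degrees mode is available because the
  original reference quantity is ambiguous.
- Starfield density/extent defaults are configurable placeholders; the
  physical display pipeline (gamma, refresh scheduling) is out of scope.
- k-means on a linearized angle is seam-sensitive (see above).
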