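# Methods

`zfhunt` re-implements, as a tested pipeline, the quantitative machinery of
a larval zebrafish prey-capture assay: video tracking of a freely swimming
larva and its paramecia, eye-vergence-based segmentation of hunting
routines, per-bout pursuit scoring, loom-contrast psychometrics, and
trial-based calcium statistics.  Because no public recordings exist for
this assay, every analysis is exercised against a synthetic-data generator
that produces the same statistical structure with exact ground truth.  This
note documents the models, the constants and their provenance, the
numerical choices, and what the synthetic validation does and does not
establish.

## Coordinate and sign conventions

Image origin top-left, x rightward, y downward; angles in degrees.  With y
pointing down, a clockwise rotation is a positive mathematical angle, so
`atan2(dy, dx)` is already clockwise-positive.  Heading 0° points along +x.
Eye angles are measured relative to heading, clockwise-positive, so nasal
rotation is positive for the left eye and negative for the right eye;
ocular vergence is `left − right` and increases during convergence.
Rightward tail bending is positive.  Target azimuth is positive toward the
fish's right; only |azimuth| enters the perceptive-field criterion.

## Free-swimming assay model

The simulated arena is a 35 mm dish imaged at 24.8 px/mm; kinematics are
sampled at 700 Hz and full-frame prey video at 17.5 Hz.  About 80 prey move
with an Ornstein–Uhlenbeck velocity process (mean speed 1 mm/s, relaxation
time 1 s, reflecting walls).  No measured paramecium diffusivity was
available, so these are plausible defaults, config-exposed.

Locomotion is bout-structured: discrete ~150 ms events with raised-cosine
displacement profiles and sinusoidal tail-beat bursts (20 Hz) under a Hann
envelope, separated by stationary pauses.  Hunting routines start as a
Poisson process (default 3/min); each routine picks a target inside the
reactive perceptive field (≤ 6 mm from the eyes-center, |azimuth| ≤ 120°),
and every tracking bout eliminates a drawn fraction of the fish–target
distance (0.2–0.5) and azimuth (0.3–0.7), so per-bout gains are exact by
construction.  Routine outcomes are drawn from a branch model: abort with
probability `p_abort` (default 0.60), otherwise an attempt that is ram
(0.25) or suction, successful with probability 0.5; aborted routines end
with a negative-gain bout with probability 0.37 and attempts contain one
with probability 0.09.  Vergence rises from the baseline mode
(15° ± 3°) to the hunting mode (55° ± 5°) through a 50 ms saccadic ramp,
with the dominant (target-contralateral) eye taking a larger share, and
relaxes over 350 ms at routine end.

Eye-angle noise is modeled as tracking jitter: AR(1)-filtered Gaussian
noise with a ~3 ms correlation time, i.e., nearly white at 700 Hz.  Jitter
whiteness matters: saccade-onset localization to 10 ms is only possible if
measurement noise decorrelates faster than the saccade rises, which is the
realistic regime for per-frame pose estimation.  Tail-angle noise is white
with 0.1° SD on the segment sum.

## Rendering

Frames are grayscale, fish and prey dark on a light background (IR
illumination polarity).  The fish is a compound of a long body ellipse and
a broad head ellipse, both with graded ("dome") intensity profiles darkest
along the midline — this is what makes the annular tail scan follow the
body axis — plus two near-black eye ellipses with softened (2 px) edges so
moment-based orientation is sub-degree, and a faint tail stroke below the
body-segmentation threshold.  Prey are Gaussian blobs (σ ≈ 2.5 px) much
lighter than the fish, as real paramecia are; this keeps an occasional
fish-prey contact from corrupting body moments.  The whole compound is
anchored at the eyes-center, and the blob's threshold-weighted centroid
offset (measured once on a fine raster) positions the drawing so the
detector's centroid lands exactly on the session's nominal body centroid.
The package-wide eyes-center offset constant (0.1 mm forward of the body
centroid) equals this measured offset.

Pose accuracy claims hold for unoccluded fish: frames where a prey particle
overlaps the fish blob are physically ambiguous (the same is true in the
real assay) and are excluded from tracker-accuracy scoring; prey-center
accuracy is scored on well-separated particles (≥ 40 px apart, clear of the
fish and its tail), since σ = 7 px smoothing deliberately merges closer
pairs.

## Tracking

Frames are background-subtracted against an exponential-moving-average
background (update rate 0.02/frame).  The body is the largest blob within
area limits above a threshold; centroid and orientation come from
above-threshold-weighted central moments, and the 180° heading ambiguity is
resolved by the sign of the third central moment along the axis (a larva's
thin tail makes the mass distribution skew-negative along the heading).
Eyes are segmented with a stricter threshold near the body centroid; of >2
candidates the two largest are kept, left/right identity assigned by the
cross product with the heading vector, and each eye's orientation (mod
180°) is reported relative to heading using the representative within ±90°.

The tail is traced by 9 consecutive annular scans from the body centroid
tailward (ring step = tail length/9), restricted to a ±60° forward sector;
the angular position of each ring's intensity extremum is localized
sub-degree by an intensity-weighted mean over the dark profile, which
handles both the narrow tail stroke and the wide plateau where the arc
crosses the body.  The 8 inter-segment angles are differences of
consecutive segment directions; their sum is the cumulative tail curvature.

Prey are local maxima of the inverted, σ = 7 px Gaussian-smoothed image
with a prominence floor and a peak-value ceiling (the smoothed fish blob
peaks far above any prey-sized particle and is rejected by the ceiling),
refined to sub-pixel by a quadratic fit.  Detections are linked
frame-to-frame by minimum-cost (Hungarian) assignment with a maximum link
distance; unmatched detections open new tracks and tracks unmatched for
more than `gap_frames` close.

## Kinematic segmentation

The hunting threshold is fit per fish: a two-component Gaussian mixture
(EM, k-means initialization, 10 restarts, tol 1e-6) on the vergence
distribution, refined by least squares against the 0.5°-binned empirical
distribution; threshold = mean − SD of the higher component.  The
refinement exists because vergence series carry a thin ribbon of
between-mode samples from saccadic transitions: maximum likelihood absorbs
that mass into the upper component and inflates its SD (biasing the
threshold by ~2–3°), whereas the histogram fit is dominated by the two
peaks.  A fit is declared degenerate — signaling a unimodal distribution —
when a component weight falls below 0.02 or the mode separation is under 3
pooled SDs.

Hunting epochs are maximal above-threshold runs with 70 ms gap-merging and
a 100 ms minimum duration.  Because the threshold crossing lags (or, with
noise, can lead) the convergent saccade, the reported onset anchors on the
steepest vergence rise near the run start and walks back along the ramp
until the slope falls below 140°/s and the trailing mean has returned to
within 2° of the local pre-saccade baseline median (the level gate keeps
momentary slope dips mid-ramp from stopping the walk early).  Offsets are taken at the threshold
down-crossing (no baseline-return extrapolation).  The dominant eye is the
one with the larger nasal rotation from pre-saccade baseline.

Bouts are detected on the Savitzky–Golay-smoothed (21 samples, order 3)
cumulative tail angle: supra-500°/s runs of its absolute derivative, 30 ms
gap-merging, 20 ms minimum duration.  Onsets/offsets are refined outward to
a 100°/s floor, bridging the brief near-zero dips between tail half-beats
with a 15 ms look-back, so reported onsets mark movement start rather than
the threshold crossing (which lags by tens of ms).  Escapes are runs of
centroid speed above 75 mm/s, computed by finite differences at the 17.5 Hz
full-frame rate without smoothing.

## Hunting analysis

Distance is measured from the eyes-center to the target; azimuth is the
angle between that vector and the heading.  A bout's distance-gain and
orientation-gain are the fractions of distance and |azimuth| it eliminated;
a bout with both negative is a negative-gain (pursuit-abandoning) bout.
Prey positions at bout boundaries come from linear interpolation of the
17.5 Hz tracks.

A prey item is the routine's target if it lies in the reactive perceptive
field at routine onset (config-switchable to the first bout onset) and both
gains of the first two bouts are positive for it.  With ~80 prey in a 35 mm
dish, neighbors of the pursued target often show incidental positive gains
on two bouts, so ties among qualifying candidates are broken by the number
of consecutive leading positive-gain bouts across the whole routine (the
pursued target stays positive; bystanders rarely do), then by summed
first-two-bout gains; multiply-qualified routines are flagged ambiguous.
Target switches are detected as a later bout pair positive for another
candidate while negative for the current target, and re-assign the target
from that bout onward.

Ram-versus-suction capture type and ingestion are consumed as annotations
(generator ground truth or a CSV); no kinematic capture classifier is
attempted because none is specified for this assay, where capture type was
scored manually.  A routine with no capture event is an abort.  Ethograms
report branch counts and probabilities (abort/attempt, ram/suction given
attempt, success given type) pooled and per fish, with sibling branches
summing to one, plus a rank-sum convenience for group comparisons on
per-fish probabilities.

## Stimuli and psychometrics

A loom simulates constant-velocity approach: θ(t) = 2·arctan((L/V)/(t_c −
t)), parameterized by L/V (0.255 s behavioral assay; 0.490 s imaging
variant) and clipped to [start, end] angle (10–100° or 10–70°).  The
matched dimming control has fixed angular size equal to the loom's final
size and dims so its solid-angle-weighted luminance change equals the
loom's at every instant: c(t) = contrast · Ω(θ(t))/Ω(θ_end) with Ω the
spherical-cap solid angle.  The nominal contrast fractions {0.2…1.0} carry
the projector lux calibration as metadata only.  The critical angular size
at escape is the loom profile evaluated at escape onset.

Escape probability versus contrast is fit by maximum-likelihood Bernoulli
logistic regression with the lower asymptote fixed at zero (no spontaneous
escapes) and the lapse rate fixed at zero by default (config flag to free
it, bounded in (0, 0.25)); slope positivity is enforced by optimizing
log β.  A parametric bootstrap (default 1000) provides a deviance
goodness-of-fit p-value and threshold confidence intervals.

## Calcium statistics

Fluorescence is z-scored per ROI over the full recording; traces with SD
below 1e-6 map to zero and are flagged.  Visual response vectors (VRVs)
concatenate, in a fixed stimulus order, the across-repetition mean response
per stimulus type; because epoch onsets are asynchronous to the 3.6 Hz
frame clock, each repetition is linearly interpolated onto a fixed
epoch-relative grid (epoch duration plus a 5 s tail).

Clustering is two-stage with correlation distance (1 − Pearson r) and
average linkage: the dendrogram cut at distance 0.1 (r = 0.9) defines
candidate clusters; members farther than 0.5 from the member-mean centroid
are pruned in a single pass (no centroid re-estimation), and clusters
keeping ≥ 5 members become archetypes.  The dendrogram is then re-cut at
0.3 (r = 0.7) and every member of those lenient clusters is assigned de
novo to the nearest archetype within distance 0.5; everything else,
including lenient-cut singletons, is unassigned.  No surviving archetype is
a valid outcome.

The convergence modulation index (CMI) of a cell: for each GO event, the
mean z-scored activity in a 4 s window centered on the convergent saccade
is compared with the means over the identical epoch-relative window in
NO-GO epochs of the same stimulus type (≥ 3 required; sample SD, n − 1;
windows truncated below 50% coverage are dropped, and events with
reference SD below 1e-6 are dropped with a flag); d_i = (X_GO − μ)/σ and
the CMI is the mean d_i over the cell's GO events, computed separately for
left- and right-dominant convergences.  CMI > 3 defines CMI+.  Sp-CMI
applies the same construction to spontaneous convergences, referenced
against window means at a deterministic grid of baseline centers drawn
from stimulus-free periods at least 4 s from any convergence.  Chance
levels come from circularly permuting each cell's trace (default 1000
random shifts) and recomputing the CMI with the event structure fixed.

"Visually responsive" has no operational definition in the source assay;
the repository convention — max |stimulus-epoch mean| above 2× the
stimulus-free SD — is exactly that, a convention, and region summaries
built on it are not a reproduction of any published responsive fraction.

## Synthetic calcium generator

The stimulus schedule interleaves whole-field light/dark flashes (3 s),
prey-like spots moving clockwise/counterclockwise (5 s), looms and
luminance-matched dimming (3 s), default 30 repetitions each with 10 s
inter-stimulus intervals.  Cells are drawn per region from a class mixture
(whole-field, spot-CW, spot-CCW, loom-phasic, loom-sustained,
dimming-nonselective, convergence-modulated; remainder silent).  Events
are placed stimulus-locked for visual classes and convergence-locked
(GO-only, preferred side) for convergence-modulated cells, convolved with
a 3 s single-exponential kernel (nuclear GCaMP6s-like; no kernel is
specified for the assay), sampled at 3.6 Hz with white Gaussian noise
(SD 1, event amplitude 5).  Spot trials are GO with probability 0.25 and
each GO trial carries one convergence, side set by the contralateral rule;
spontaneous convergences occur at 1/min in stimulus-free periods.  The
published behavioral GO rate in the tethered assay is much lower (~6%),
but at that rate a desk-scale session (tens of repeats) contains ~0 GO
events and the CMI is undefined; the generator's defaults are chosen so
that per-side GO counts (~5) and NO-GO reference counts (~45) make the
CMI statistically meaningful, which is the property the validation needs.

## Problem sizes used in validation

Validation sessions are 30–60 s at 700 Hz with hunting rates of 6–10/min
(pooling sessions until, e.g., 500 routines or 1000 frames are reached),
50 sessions for threshold recovery, 100 replicate cohorts for ethogram
power, three imaging sessions (~200 cells each) for CMI separation and 500
noise cells for false-positive calibration.  These sizes make every check
reproducible on a laptop; they are choices of the package, config-exposed.

## What passing tests show — and what they do not

The synthetic generator shares the analyses' statistical assumptions by
construction: clean bimodal vergence, well-separated tail beats, Markovian
outcomes, linear-interpolatable prey paths, white imaging noise and
exponential calcium kernels.  Passing tests therefore demonstrate that the
implementations are correct and self-consistent (parameter recovery,
invariances, exact arithmetic), not that they are robust to everything real
data contains: occlusions and reflections, non-stationary backgrounds,
skin-pigment artifacts, overlapping prey, eye-tracking glitches,
slow-drifting fluorescence baselines or correlated noise.  Thresholds for
real recordings (intensity thresholds, area limits, merge gaps) will need
dataset-specific adjustment through the config layer.

## Known limitations

- No kinematic ram/suction classifier; capture annotations are an input.
- The renderer's fish is rigid except for the tail stroke: a strongly bent
  tail is not reflected in the body/head shapes, so tail-tracer accuracy is
  validated on standalone rendered arcs rather than on bent full-fish
  scenes.
- Hunting epochs and bout-level analysis assume the 700 Hz kinematic
  channel; the pipeline does not segment hunting from video alone.
- `run_pipeline` analyzes one synthetic session per call; multi-fish batch
  orchestration is left to the CLI user.
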