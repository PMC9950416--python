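# Methods

This note documents the models, conventions and numerical choices
behind `rungwalk`, and what the synthetic fixtures do and do not show
about real recordings.

## Course geometry and coordinates

The course is parameterized by `CourseGeometry`: eight 2 cm steps
separated by 4 cm gaps spanning 48 cm, with the two adjacent interior
steps (indices 3 and 4) manipulable. Assay coordinates are cm along
the travel axis (x) and cm above the step-top surface (height, upward
positive); image coordinates are pixels with the origin top-left and y
downward, converted through `px_per_cm` with the height negated. The
full-scale camera defaults are 1280×680 px at 120 Hz with 24 px/cm;
tests and examples use a reduced geometry (312×156 px at 60 Hz,
6 px/cm) so that rendered-video fixtures stay fast — the physical
course is identical and every algorithm is resolution-independent, so
results transfer up to scale.

## Protocol scheduler

The day plan is fixed: habituation (day 0), stable (1–4), a transition
day with exactly 20 stable trials before the center steps are released
(5), unstable (6–10), a transition with 20 unstable trials before
relocking (11), stable (12), per-trial randomized state (13–16), and a
final all-released challenge session (17). Randomized days draw each
trial i.i.d. Bernoulli with p(unstable) = 0.5; only these days consume
randomness, so schedules are reproducible from a seed and all other
days are seed-invariant. Trials per session default to 60 (a
compromise within the range real sessions produce; ECoG sessions ran
longer).

## Crossing generator

A crossing is a nose trajectory at a base speed of 12 cm/s (lognormal
per-trial jitter, σ = 0.05) from one course end to the other. On
unstable walk trials the speed is multiplied by 0.8 after the first
manipulated step, giving transition-day crossing times and
speedup-index signs of the expected order. The posture offset — where
the nose is, relative to the near edge of the first manipulated step
and the base nose height (3.5 cm), at the moment the forepaw contacts
it — is drawn from a Gaussian whose defaults are the observed condition
statistics: progression 0.77 ± 0.93 cm / height 0.61 ± 1.02 cm on
stable trials and −0.25 ± 0.73 / −0.25 ± 0.69 cm on unstable trials.
The distribution family is an assumption (nose positions at the step
were reported to be normally distributed); draws are clipped at ±3 cm
so rendered paths stay in frame. In history mode (randomized days) the
current state has no effect and the mean shifts by ±(0.10, 0.07) cm
according to whether both previous trials were stable or unstable,
matching the history-conditioned condition means; mixed histories
center on zero.

Paw contacts are placed kinematically: the forepaw contacts step k
when the nose passes its near edge (plus the posture offset on the
trigger step); the hindpaw when the nose is 9 cm further along — which
is exactly why hindlimb activations fail the head-position constraint.
The jump strategy (probability per animal, default 0) omits all
center-step contacts. Slips are per-gap Bernoulli events, mostly
hindlimb. Contact sides alternate left/right.

What the generator does **not** emulate: limb kinematics beyond
contact timing, body-shape variability, lighting changes, occlusions,
whisking, or the physics of step rotation (the state is binary).
Passing tests therefore demonstrate the correctness of the analysis
chain given its stated detection model, not robustness to arbitrary
real-world video.

## Rendering and ROI traces

Rendered frames are a static background (dark arena, brighter step
pillars) plus a bright ellipse body with a triangular nose protrusion
whose apex is the ground-truth nose, and brief bright paw dots at
contact/slip locations. The body rides 1 cm above the nose so it
stays clear of the thin step-surface ROI bands; fixtures that exercise
event detection on rendered video use a moderate height-offset spread
(σ ≈ 0.4 cm) for the same reason. The lighter alternative,
`synthesize_roi_traces`, skips rendering and writes each contact as a
smoothed rectangular pulse directly onto the corresponding ROI trace
(σ = 12 ms smoothing, well under the 100 ms pulse so rising edges stay
sharp).

## Tracking

The background model is the pixel-wise temporal median of subsampled
frames — exact when the animal occupies each pixel in fewer than half
the samples. Segmentation thresholds the absolute difference
(default 30 intensity units, calibrated on the renderer's contrast),
labels 8-connected components, and keeps the largest above 30 px.
Ellipse parameters come from the second central moments of the mask
(a uniform ellipse with semi-axes a, b has variances a²/4, b²/4);
collinear components get minor axis 0 and a degeneracy flag. The nose
is the mask pixel with maximal projection on the major axis oriented
by the recent centroid displacement (falling back to a configured
heading before the animal moves); ties resolve to the pixel nearest
the axis. Whether thresholding precedes or follows background
subtraction was an open choice; absolute-difference-then-threshold is
used.

## Event detection

Crossings are maximal runs of valid poses, tolerating up to 0.25 s of
missing frames, whose endpoint nose positions straddle the course
midline. Step detection takes the first local maximum of the first
difference of a step-surface trace above a threshold; the default
threshold is 5× the median absolute first difference (falling back to
a quarter of the maximum difference for noise-free traces, where the
median is zero). Local maxima are strictly greater than both
neighbors; plateaus resolve to their earliest frame. Validation
requires the nose (optionally the ellipse centroid) to be before the
near edge of the next step in the travel direction. Slip candidates
apply the same peak detection to gap ROIs with every peak kept and no
head constraint — zero false negatives by construction — and are
confirmed by joining an external annotation table, mirroring the
semi-automated manual review. Paw-side classification encodes step
frames as 32-bin brightness histograms clustered by seeded K-means
(10 restarts); the cluster → left/right mapping comes from a few
labeled frames, standing in for manual label correction.

## Behavioral metrics

Crossing time is (end − start)/frame rate; the skilled-performance
criterion is a session mean strictly under 8 s (1 s per obstacle).
Transition sessions split into the 20 trials immediately preceding the
change and the remainder. Posture progression is measured from the
near edge of the first manipulated step; heights are re-referenced to
the per-animal mean nose height over the analyzed trials (both
references are configurable, since the plotted origin is a convention).
Speed profiles use one spatial segment per step-plus-gap interval
(margins folded into the end segments); a segment counts only when
both boundary passages are observed. The baseline is the per-trial
mean speed over approach segments — those strictly before the first
manipulated step in the travel direction (a per-session baseline is
available as an option). The speedup index is the sum over segments
of mean stable minus mean unstable baselined speed, so positive values
mean slower unstable crossings; it is exactly antisymmetric under
exchanging the condition labels. Animals whose probability of skipping
both center steps exceeds 0.5 are flagged as jumpers and excluded from
history-conditioned posture analyses (the cutoff is a package choice;
only the exclusion itself was prescribed).

## Ethogram statistics

Ethograms are non-overlapping intervals of compensation, investigation
and halting, with onset 0 at first contact; overlapping annotations
are rejected at load with a truncate-to-earlier repair suggestion.
Dominance and the halting fraction are evaluated over a window whose
default is 5 s ("the first few seconds"); duration ties resolve to the
earliest-onset category, and the one-third criterion is strict. The
Yates-corrected χ² uses the closed form with the continuity correction
floored at zero, so identical rows give a statistic of exactly 0; the
test is validated against an independent implementation and its
conservatism is checked by simulation. The pooled t-test accepts
either raw samples or printed summary statistics, and the two forms
agree to machine precision by construction.

## Evoked potentials

Strobe falling edges (threshold at half the signal range, one-sample
debounce) are paired one-to-one with hardware frame counters; counter
wraparound is unwrapped monotonically and dropped frames remain holes
rather than being interpolated. Epochs are 250 ms pre / 500 ms post
the contact frame at whatever sample rate the recording declares
(1 kHz in the simulator — ample for a 50 Hz low-pass analysis).
Filtering is a 4th-order Butterworth applied forward and backward
(zero phase; effective magnitude is the squared single-pass response)
with at least three filter lengths of reflective padding; baselining
subtracts the per-channel mean of the 250 ms before the event.
Channels are excluded when their broadband variance exceeds 10× the
median channel variance or their impedance exceeds a limit — a rule
standing in for the qualitative "wide amplitude, random oscillatory
behavior" criterion. ERPs are pointwise means per (paw side × trial
state) condition with a 95% pointwise normal interval of the mean;
peaks are signed extrema in a 0–200 ms search window, measured
per channel or on the channel-pooled mean.

The simulator injects, on the anterior half of the channels and only
for contralateral-paw events, a Gaussian negativity plus (for the
unstable condition) a delayed alpha-function rebound; the defaults are
−100 µV at 10 ms (σ = 5 ms) for stable steps and −300 µV at 70 ms
(σ = 10 ms, +300 µV rebound decaying over 200 ms) for unstable ones.
The rebound starts 3σ after the peak so the noise-free waveform value
at the peak latency is exact. White noise defaults to σ = 50 µV
(1/f noise available); recovery fixtures use 40 trials, below the ~75
trials per session the extended recordings yielded but sufficient for
the stated tolerances. The narrow stable transient loses ~10% of its
amplitude to the 50 Hz two-pass filter — visible in the worked
example — which is a property of the analysis, not an error of the
simulator.

## Lesion volumetry

Volumes are Cavalieri estimates: the absolute shoelace area of each
traced outline times the slice thickness (default 0.1 mm), summed per
hemisphere; outlines flagged as holes subtract. Self-intersecting
polygons are rejected. Slice alignment is assumed done upstream (the
tracing workflow is manual), and sectioning orientation is irrelevant
to the estimate. Phantoms sample cylinder/box/ellipsoid cross-sections
at slice centers with 128-gon circles (inscribed-polygon area error
< 0.05%), giving midpoint-rule convergence of order h²; box phantoms
are exact. Classification is "large" strictly above 15 mm³.

## Problem sizes in tests and the acceptance script

Fixture sizes are chosen as the smallest that make the statistical
assertions meaningful: the cohort analysis uses 22 synthetic animals ×
20 trials per state at the reduced geometry; tracking evaluation
renders 4 crossings; ERP recovery averages 40 trials; phantom stacks
use 10–30 slices. All randomness flows from explicit seeds.

## Known limitations

- Tracking assumes a single animal and a high-contrast blob; there is
  no markerless limb pose estimation.
- Slip confirmation is deliberately semi-automated: the detector is
  tuned for recall and defers precision to the annotation table.
- The ethogram module consumes manual annotations; it does not
  classify behavior from video.
- The step-rotation physics, reward hardware and acquisition
  electronics are outside the simulators' scope.
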