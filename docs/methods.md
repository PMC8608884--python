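# Methods

`pigpheno` quantifies five behavioral/physiological assays of juvenile
minipigs — open-field exploration, novel-object recognition, baited ball-pit
foraging, circadian actigraphy, and treadmill-free runway gait — from four
text data streams: pose-estimation coordinate tables, manually annotated
event logs, wearable step counts, and 3D motion-capture marker tables.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not establish.

## Coordinate conventions

Image pixels are y-down.  All open-field geometry is computed in *arena
coordinates*: origin at the door-wall/left-wall corner, x along the door
wall, y away from it (y-up), units meters.  The conversion happens exactly
once, in `ArenaGeometry`, from a declared px/m calibration and the pixel
position of the origin corner (the calibration can be derived from the two
door-wall corner pixels and the known 1.83 m side length; the camera is
assumed axis-aligned with the arena).  Mocap marker positions are used as
exported, in meters in the lab frame, z up.

Acquisition rates are deliberately *required* inputs, not defaults: the
camera and mocap rates are properties of the recording hardware, and
guessing them silently corrupts every distance-per-time quantity.

## Open field

* **Confidence filtering.** Pose points below a likelihood threshold
  (default 0.9) become missing; interior missing runs of at most `max_gap`
  frames (default 10, i.e. a third of a second at 30 fps) are linearly
  interpolated, longer runs stay missing.  These defaults follow common
  pose-estimation practice; both are config-exposed.
* **Distance.** Sum of Euclidean steps between consecutive valid frames of
  the chosen body part (back of the head by default).  A missing run
  contributes the straight-line distance across it — a lower bound on the
  unobserved path, preferred over dropping the segment because it never
  inflates distance.
* **Occupancy.** Normalized 2D histogram over the arena; 61x61 bins by
  default (~3 cm cells) so the 30 cm door band spans ten cells.
  Out-of-arena points (calibration slop) are clamped to boundary cells and
  counted, not dropped.
* **Door zone.** The full-width band of depth 0.30 m along the door wall.
  Dwell is the fraction of valid frames inside the band; seconds are that
  fraction of the session duration.
* **Escapes** are consumed from manual annotation files.  The study scored
  them by eye; detecting "pushing on the walls" from a single overhead
  point would invent a behavior definition the data cannot support.

## Novel object and ball pit

Contact bouts are annotated intervals labeled `novel`/`familiar`.
Same-label overlaps are merged (annotator slop), cross-label overlaps are
both counted — scored time is never silently dropped, a warning is logged.
The summary reports cumulative seconds, percentage of total contact time,
and the discrimination index (novel − familiar)/(novel + familiar).

Ball-pit trials hold at most six instant `retrieval` events within a 300 s
cap (the assay lasts under five minutes).  The first latency is measured
from trial start — the assay has a defined start and the first search is
part of the behavior; this choice is visible in the API (`trial_start`).
The trial's mean latency is the mean of available latencies, so with all six
retrievals it equals (last retrieval − start)/6.

## Circadian actigraphy

Step counts are summed into 15-min bins per calendar day; only days covered
midnight-to-midnight (to within one bin) enter the daily profile, which is
the across-day mean per bin.  The peak window is the contiguous window of a
given width (4 h default) with maximal mean binned activity, found by
exhaustive scan; ties break to the earliest start.

Sleep segmentation works per *night*, defined noon-to-noon so a bout that
crosses midnight is never split; a night belongs to the day it starts.
Within a night, a *quiet run* is a run of at least `min_run` bins (default
4 bins = 1 h) with at most `threshold` steps (default 0).  Sleep onset is
the start of the first quiet run beginning inside the evening search window
(19:00–03:00), wake is the end of the last quiet run ending inside the
morning search window (05:00–11:00); the search windows bracket the
housing's 07:00–19:00 light cycle and are config-exposed.  Brief nocturnal
movement (shorter than `min_run`) therefore cannot break a night.  A night
lacking either mark is flagged undetermined — never imputed.  Because the
study scored sleep from tracker data *and* night-vision video without
stating a fusion rule, the package offers activity-only segmentation plus
direct import of annotated onset/wake times, and does not guess a fusion.

## Gait kinematics

Each rigid pod carries three markers.  Per frame, the pod frame is: origin
at the marker centroid; perpendicular axis = unit normal of the marker
plane, signed toward global up at the first frame and by continuity
afterwards; anterior axis = in-plane unit direction from centroid to a
designated front marker; medial-lateral axis completing a right-handed set.
The rotation from the reference frame (first valid frame) to each frame,
expressed in the reference pod axes, is decomposed as intrinsic z–y′–x″
Euler angles: yaw about the base-perpendicular axis, pitch ("nodding")
about the medial-lateral axis, roll ("lateral tilt") about the anterior
axis.  The order matters only under large simultaneous angles and is
config-visible.  Angles are unwrapped; frames with |pitch| > 85° are flagged
(decomposition ill-conditioned).  Reported *ranges* are peak-to-peak
(max − min), explicitly labeled as such since "a range of 12°" is ambiguous
between peak-to-peak and ±amplitude.

Marker noise is suppressed before frame construction with a zero-phase
Butterworth low-pass (`sosfiltfilt`, default order 8), padded by several
filter time constants because steep low cutoffs otherwise leak edge
transients.  For walking trials with a ~1 Hz stride, pod-orientation content
concentrates at the stride frequency, so a 1.5 Hz cutoff passes the signal
(attenuation < 0.2%) while removing most of the broadband marker noise; the
cutoff is a parameter and `None` disables filtering entirely (the right
choice for clean data, since any filter slightly biases a peak-to-peak
range).  Average linear velocity — net displacement of a pod origin over
elapsed time, the headline speed — is computed from the *unfiltered*
centroid: net displacement needs no smoothing and filter edges would bias
the endpoints.  Path-length/time is reported separately as "mean speed".

Touchdowns are stance onsets: the leg marker's vertical position falls into
the lowest 15% of its excursion *and* its forward-difference speed falls
below 10% of its peak, sustained for at least 2 frames.  Forward (not
central) differences matter here: at the touchdown frame the foot has
already stopped, while the central difference still mixes in the last swing
step and shifts every onset by one frame.  Non-stance blips of up to 3
frames inside a stance run are bridged (a real swing phase cannot last
30 ms).  A run already in stance at the first frame has no observed onset
and produces no event.  One gait cycle is the touchdown sequence
LH → LF → RH → RF, matched greedily left-to-right with each touchdown used
at most once; simultaneous touchdowns resolve in pattern order and a new
cycle's LH must fall strictly after the previous RF.  A trailing partial
match is returned flagged incomplete.

## Caption statistics

Pearson r, the pooled unpaired t-test (Welch by flag) and simple linear
regression are implemented from their closed forms; only tail probabilities
come from the t distribution.  The Gaussian fit is
`baseline + amplitude*exp(-(x-mean)^2/(2 sd^2))` by least squares with
multi-start initialization (moment-based start plus randomized restarts);
baseline is included by default because behavioral duration series have a
non-zero floor, and a 3-parameter variant is selectable.  Non-convergence
is a flag on the result, never silent.  For a t-test the explained-variance
companion is reported as eta² = t²/(t²+df) and labeled as such.

## Synthetic data: what it emulates, what it does not

Every generator is a pure function of (parameters, seed); a single global
seed fans out to fixed per-stream substreams, so adding a generator never
perturbs existing data.  Ground truth (exact realized path length, door
fraction, bout seconds, touchdown times, and so on) is recorded beside each
dataset and serialized to YAML.

* **Open field**: a reflected Gaussian random walk (default step SD 1 cm at
  30 fps, giving ~220 m in a 10-min session, the study's scale).
  `door_bias` is the *target door-zone occupancy fraction*: positive values
  switch between a door-band walk and a complement walk with exit rates
  chosen so the stationary door fraction equals the bias; 0 gives a plain
  whole-arena walk whose long-run occupancy is uniform.  The state switch
  relocates the walker, so biased tracks contain occasional long steps —
  path-length ground truth records exactly what was generated.
* **Contacts/retrievals**: exponential bout durations with Bernoulli labels;
  weekly retrieval latencies around a linearly decreasing schedule
  (26.5 → 7.8 s across 18 weeks, the study's endpoints).
* **Actigraphy**: minute-resolution Poisson counts — zero during programmed
  sleep, elevated in the peak window, baseline otherwise, with optional
  short nocturnal bursts placed > 1 h inside the sleep bout.
* **Gait**: three rigid pods advancing at constant speed with small lateral
  sway, orientations driven by zero-phase sinusoidal yaw/pitch/roll
  (range = 2x amplitude); four limb markers with linear-advance swing and
  flat stance, touchdowns at quarter-stride offsets in LH→LF→RH→RF order.
  At the default 100 frames/s and 1 Hz stride, sinusoid extrema fall exactly
  on sample instants, so noiseless ranges are exact rather than
  sampling-limited.  Marker noise is isotropic Gaussian specified by its
  RMS 3D residual (the convention mocap vendors use); 1 mm is a typical
  calibrated-volume residual.  Pod triads are ~24 cm isoceles triangles,
  elongated along the anterior axis so the yaw estimate keeps a long lever
  arm.

None of the generators model behavioral autocorrelation beyond these
mechanisms, posture, biomechanically realistic limb dynamics, device error,
or inter-animal variability.  Passing recovery tests therefore shows the
*analysis* is correct under known generating processes at realistic
magnitudes — not that the generators reproduce pig behavior.

## Problem sizes

Test and demonstration runs use one 10-min open-field session (18,000
frames), 200 contact bouts, 18 weekly retrieval trials, 5 days of
minute-resolution actigraphy, and a 10.25 s gait trial at 100 frames/s —
the scale of one animal's data in the study design.

## Known limitations

* The pose dialect ingests the common three-header-row CSV and a flat
  variant; binary exports (.mat, C3D, HDF5) are out of scope.
* Sleep timing resolution is one bin (15 min by default); sub-bin onsets
  are rounded toward the quiet side.
* Euler decomposition near |pitch| = 90° is flagged, not repaired; pod
  mounting should keep pitch well away from vertical.
* The t-test/regression layer deliberately omits repeated-measures and
  mixed-effects structure (the study reports none) and applies no
  multiple-testing correction (likewise); both omissions are documented
  rather than silently "improved".
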