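# Methods

## Signals and preprocessing

A recording is a 120 Hz stream of eye-in-head unit directions, head
orientation quaternions (head-to-world, w-x-y-z), head position, and a
per-sample validity flag (validity derives from pupil detection; the
tracker interpolates positions, so the flag, not the value, is
authoritative).  Invalid samples and a 40 ms margin on either side are
masked as noise and excluded from all classification; the margin is
rounded **up** to whole samples (5 each side at 120 Hz) so the full 40 ms
is always covered.  Masked samples are never interpolated.

Speeds are backward differences assigned to the later sample (the first
sample copies the second): eye speed from successive eye-in-head
directions, head speed from the geodesic angle between successive
quaternions (double-cover safe: computed as 2·atan2(|vec|, |w|) of the
relative quaternion), gaze speed from successive world-frame gaze
directions, where gaze = head rotation applied to the eye-in-head
direction.  Composition, not a sum of components, is used for gaze: it is
the physically correct combination of eye and head motion.  All three
speed traces are smoothed with a five-sample (40 ms) running median;
edges use shrunken windows so no padding values are invented.  Head pose
is assumed resampled onto eye timestamps; `kinematics.resample_pose`
provides nearest-neighbour alignment (≤ half a 90 Hz frame of skew) for
streams recorded at different rates.

## Classification

Thresholds (deg/s) with stationary-head defaults: θ_saccade = 35,
θ_lowgaze = 10, θ_loweye = 10, θ_head = 7.  Eye/gaze thresholds are scaled
by the concurrent head speed, θ_scaled = (1 + v_head/60)·θ.  θ_head is
deliberately **not** scaled — scaling a head criterion by head speed would
be self-referential.  A high-gaze threshold field exists but is unused by
the default tree.

Saccade detection runs first: maximal runs of usable samples whose eye
speed strictly exceeds the per-sample scaled saccade threshold, kept when
the run spans ≥ 20 ms.  Run duration follows the sample-ownership
convention (each sample owns the preceding inter-sample interval), so a
k-sample run at 120 Hz lasts k/120 s.  Runs are never bridged across
masked samples.  Saccade amplitude is the angle between the world-frame
gaze directions at the run's first and last usable samples — the size of
the *gaze shift*, which is what the 3° exclusion targets — and peak
velocity is the maximum eye speed inside the run.  Saccades with
amplitude < 3° or peak velocity ≥ 1,000 deg/s are relabeled
`excluded_saccade` and stay excluded; they are not merged into the
surrounding interval.

Each maximal usable run between saccades is tiled left-to-right with
100 ms abutting epochs.  A trailing remainder ≥ 50 ms becomes its own
short epoch; a smaller remainder is merged into the preceding epoch; an
interval under 50 ms with no epoch is `unclassified`.  Epoch statistics
are means of the median-filtered speeds over the epoch's samples (mean
rather than median; configurable).  The decision tree, with ties at exact
threshold equality resolving to the slower branch:

    gaze ≤ θ_lowgaze-scaled ?  →  head ≤ 7 ? fixation : vor
    otherwise                  →  eye ≤ θ_loweye-scaled ? head_pursuit
                                  : head ≤ 7 ? smooth_pursuit : sp_vor

θ_loweye is not printed in the running text of the source algorithm's
description; it defaults to 10 deg/s, scaled like the gaze threshold, and
is configurable.  Scaling inside saccade detection uses the per-sample
head speed ("all time points"); inside epoch classification, the
epoch-mean head speed (per-window decision).

## World geometry and paradigm

Distances are meters, angular sizes dva: size(e, d) = 2·atan(e/2d).  The
recentering cross (0.18 m ≈ 0.94 dva) sits 11 m ahead; two concentric
rings of eight 1 m disks at 6 dva (parafoveal) and 20 dva (peripheral)
eccentricity surround it.  Eight disks per ring is a design choice (the
count is not stated in the source design; eight gives every disk a
diametric opposite) and is configurable.  Ring lateral radius is fixed at
cue time (d·tan(ecc)); rings are fronto-parallel.  Static trials cue
disks at 13 or 32 m; dynamic trials cue at 32 m while the observer
translates forward at 5 m/s (modeled as observer motion over a static
world — equivalent by relativity to moving disks).  The schedule holds
288 trials in 6 counterbalanced blocks of 48 (two per condition:
static-13, static-32, dynamic; Latin-square rotation per participant
index), eccentricity and target direction balanced within block, SOA
uniform on [0.6, 1.6] s, deterministic per seed.  Cue-to-cue spacing is
uniform on [5.4, 7.4] s, giving the paradigm's 6.4 s mean trial spacing
(the distribution is artifact-defined).

## Synthetic sessions

Each trial: cross fixation → cue-triggered saccade (latency ~ N(200, 30) ms)
→ on-target fixation (static) or pursuit (dynamic) → target onset after
the SOA → button response (~ N(450, 80) ms after target) → return saccade
to the cross.  Saccades follow a raised-cosine velocity profile with
main-sequence peak v_peak = 500·(1 − exp(−A/14)) deg/s; the profile
duration 2A/v_peak makes the waveform integrate exactly to the amplitude
and keeps every ≥ 3° saccade longer than 20 ms.  Pursuit follows the cued
disk's instantaneous angular velocity at gain 0.95 along the disk's
path; accumulated lag beyond 1.5° triggers a catch-up saccade (rare under
defaults).  Peripheral gaze shifts recruit the head: a minimum-jerk
rotation carrying 30% of the shift, onset timed so head speed peaks
200 ms after the eye's peak; once gaze is on target the eye
counter-rotates at VOR gain 0.95, the 5% leak appearing as slow gaze
drift.  Parafoveal shifts leave the head still.

In dynamic trials gaze stays on the approaching disk until it closes to
12.5 m (~3.9 s after cue) before the return saccade.  This emulates the
observed behaviour the validation regime requires — on-target gaze speeds
only reach the high single digits (peripheral) late in the approach, and
an early return would leave peripheral pursuit as slow as parafoveal.  A
side effect is that synthetic dynamic trials disengage *later* than
static ones; the generator does not attempt to reproduce observed
disengagement-time orderings (inferential statistics on RTs are out of
scope).

Fixational noise is white angular jitter on the eye direction, low-passed
at 20 Hz, with SD calibrated at run time so the median-filtered eye speed
during fixation averages ~2 deg/s — safely below every threshold.  Head
jitter is not simulated.  Dropout arrives in bursts of geometric length
(mean 3 samples) at an expected 6% of samples, mimicking blinks and
tracker losses; with the 40 ms noise padding this masks roughly a fifth
of each session, as it would for real short dropouts.

**Ground truth is kinematic.**  The per-sample truth label is the label
the threshold taxonomy assigns to the *noise-free* generated speeds
(scripted saccade windows are truth-saccades only where the noiseless eye
speed clears the scaled threshold; elsewhere the decision tree applies).
Slow parafoveal pursuit is therefore truth-labeled *fixation* — by
design: a speed-threshold taxonomy cannot define slow pursuit as a
distinct kinematic state, and that failure is exactly what the behavioural
`phase` and foveated-`object` columns, carried separately, make
measurable.  Consequences for interpreting the tests: label-recovery
rates measure the implementation against an ideal thresholder, not
against behavioural intent; the behavioural comparison lives in the
ray-cast validation.

What the generator does not emulate: vergence and depth accommodation,
torsion, pupil dynamics (constant 3.5 mm), saccadic suppression
artifacts, head tracker noise, variable frame rates, and subject-level
idiosyncrasy (one parameter set per session).  Passing tests therefore
show the pipeline is correct under idealized kinematics with realistic
noise and dropout, not that its thresholds are optimal for any particular
tracker.

## Validation measures

Ray casting intersects the gaze ray with spheres (disk orientation is
unspecified in the source design, so disks are spheres of the disk
radius; the cross a sphere of half its size); the nearest hit wins.
Pursuit percentages are over usable (non-noise) samples, pooled across
trials; empty categories report "absent" (None), never 0.  "Pursuit"
combines smooth pursuit, smooth pursuit with compensatory VOR, and head
pursuit for the headline figure; smooth-pursuit-proper rates and a
per-label breakdown are also emitted.  The on-target gaze-speed follow-up
selects, per trial, the longest intersaccadic interval whose modal
ray-cast label is the cued disk and averages gaze speed over its usable
samples with eye speed ≤ 20 deg/s (excluding catch-up residue).
Saccadic RT uses the first included (≥ 3°) saccade after cue onset;
button RT the first response between target onset and the next cue;
disengagement the first post-target departure of the ray-cast label from
the cued disk.  Because generated saccades have finite flight time, the
ray-cast departure trails the scripted return-saccade onset by the time
gaze needs to traverse the disk's angular radius (a few samples); tests
bound this rather than asserting exact equality.

Saccade recovery is reported over *detectable* injected saccades — those
retaining a usable run of at least the 20 ms minimum duration after
dropout masking.  A saccade obliterated by masked samples is never
presented to the classifier (noise epochs are excluded outright), so
counting it against the detector would measure the dropout process, not
the detection.

## Numerical choices

* Epoch tiling, padding rounding, and run-duration conventions as above;
  float comparisons guard with 1e-9 epsilons.
* Threshold ties resolve to the slower branch (deterministic; the
  boundary has measure zero under noise).
* Saccade detection uses strict `>` (equality is not a saccade).
* The brute-force detector oracle in the tests is an explicit per-sample
  Python scan, independent of the vectorized implementation.
* CSV round trips are exact to 1e-9 (12 significant digits written).

## Problem sizes

The test suite and acceptance script simulate the full 288-trial session
(~221k samples) for the noisy-session checks, a 96-trial mixed
static/dynamic subset for the noiseless checks, and 300–1,000 random
traces of up to 2,000 samples for the detector oracle; these sizes give
stable percentages (hundreds of saccades, tens of thousands of epochs)
while keeping a full run in seconds.
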