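# vrgaze

Eye/head/gaze movement classification for head-mounted-display (HMD) eye
tracking in virtual environments, with ray-cast ground-truth validation and
a synthetic session generator.

## The problem

When observers are free to move their heads, gaze shifts are carried by eye
and head together, and monitor-era event detectors break down.  This
package implements a threshold classifier for 120 Hz HMD eye tracking that
distinguishes six oculomotor states from three angular speed signals:

* **eye speed** — angular velocity of the eye relative to the head (deg/s),
* **head speed** — angular velocity of the head relative to the world,
* **gaze speed** — angular velocity of the world-frame line of sight
  (head rotation applied to the eye-in-head direction).

Every eye/gaze threshold θ is scaled by the instantaneous head speed
v_head:

    θ_scaled = (1 + v_head / 60) · θ

**Saccades** are detected first: runs ≥ 20 ms where eye speed exceeds
θ_saccade-scaled (θ_saccade = 35 deg/s); saccades under 3° of gaze
amplitude or with peak velocity ≥ 1,000 deg/s are relabeled
`excluded_saccade`.  Intersaccadic intervals are tiled with 100 ms epochs
and labeled by a decision tree over epoch-mean speeds: gaze below the
scaled low-gaze threshold (θ_lowgaze = 10 deg/s) splits into **fixation**
vs. **VOR** on head speed (θ_head = 7 deg/s); moving gaze splits into
**head pursuit** (quiet eye), **smooth pursuit** (quiet head), or **smooth
pursuit with compensatory VOR**.

Validation uses the virtual environment itself: an imaginary ray along the
gaze direction is intersected with the scene to name the foveated object
per sample.  Samples foveating a stationary object should never be labeled
pursuit; samples tracking a moving disk should be.  The synthetic session
generator (`vrgaze.simulate`) reproduces the cued visual-discrimination
paradigm — 288 trials, two disk rings at 6 and 20 dva, 600–1,600 ms
cue–target SOA, dynamic trials with 5 m/s ego-motion, ~94% sample validity,
main-sequence saccades with head contributions lagging the eye by
~200 ms — so the entire pipeline is testable without any recordings.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_classify.py
python analysis/03_validate.py
python analysis/04_behavior.py
```

The drivers simulate the full session into `scratch/session/`, classify
it, and write summaries under `results/`.  Output of a run (seed 1):

```
simulated 288 trials: 220670 samples over 1839 s, 94.3% valid
18209 segments: {'fixation': 13233, 'noise': 3375, 'saccade': 454, ...}
epoch-label agreement with ground truth: 98.3%
saccade recovery: 452/492 detectable true saccades (91.9%)
pursuit-labeled time on static objects: 0.10% (moving: 2.72%)
smooth-pursuit rate on the cued disk: dynamic peripheral 5.28%,
    dynamic parafoveal 0.13%, static 0.19%
mean on-target gaze speed (deg/s):
dynamic parafoveal 2.9   dynamic peripheral 6.3   static ~2.0
```

Reading those numbers: the classifier recovers nearly all injected
saccades and epoch labels, and almost never calls static fixation
"pursuit" (0.10%).  But smooth-pursuit detection works only where the
target's angular velocity drives gaze speed over the scaled 10 deg/s
threshold: peripheral disks approached at 5 m/s sweep fast enough late in
the trial (5.3% of on-target time labeled smooth pursuit), while
parafoveal disks never do (0.13%, a 40× drop) — slow smooth pursuit is
kinematically indistinguishable from fixation under pure speed
thresholds.  The on-target gaze speeds in the last rows show why: ~2.9
deg/s parafoveal tracking sits far below threshold.

A command-line interface wraps the same library:

```sh
vrgaze simulate --seed 1 --trials 24 --out-dir scratch/demo
vrgaze classify --recording scratch/demo/recording.csv --out scratch/demo/segments.csv
vrgaze validate --recording scratch/demo/recording.csv \
    --events scratch/demo/events.csv --out-json scratch/demo/report.json
```

## Layout

```
src/vrgaze/        io, kinematics, classify, paradigm, simulate, validate, cli
analysis/          numbered narrative drivers over the library
tests/             unit, property (hypothesis), and end-to-end suites
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical choices, limitations
```

Coordinates are left-handed, y-up, z-forward (game-engine convention);
quaternions are (w, x, y, z), head-to-world; timestamps are seconds from
recording start.
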