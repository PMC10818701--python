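# Methods

## Problem setting

A worker wears a single IMU at the waist, sampled every 0.1 s. Each record
carries seven fields (date, time, three acceleration axes, pitch, roll) and
a status label: 0 *safe*, 1 *fall* (fall from height), 2 *stumble*
(ground-level trip), 3 *coma* (prolonged post-collapse stillness). The task
is to raise alarms for the three accident classes while suppressing false
alarms from field conditions that mimic them — uneven or gravel surfaces,
stairs, slopes, motorcycle rides over bumps, and quiet seated rest.

Acceleration is kept in units of g throughout, so the thresholds have
physical readings: the stationary signal magnitude is ~1, free fall pulls
the magnitude toward 0, and ground impacts reach several g.

## Features and windowing

Three derived channels supplement the five raw ones:
`SVMa` (Euclidean norm of the acceleration axes), `ΔSVMa` (its one-step
difference; 0 for the first sample of a recording, otherwise always the
difference to the preceding raw sample, so no window is discarded), and
`SVMo` (norm of pitch and roll; the package's reading of the
rotation-angle magnitude — the exact formula is not documented in the
emulated protocol and is flagged as an assumption).

Windows are 20 samples (2 s) long with stride 1 and take the label of
their 10th sample, counting from 1. The 1-based convention is pinned by
two boundary cases that the tests enforce: a 20-sample recording yields
exactly one window labelled by sample 10, and a 21-sample recording yields
a second window labelled by sample 11. Windows never cross recording
boundaries, so a participant-level train/test split can never leak samples
across the split. Which channels the original classifier consumed is
unknown; the default set `(ax, ay, az, pitch, roll, SVMa, ΔSVMa, SVMo)` is
configurable.

## Scenario simulator

The original recordings were destroyed under the study's IRB consent, so
the simulator is a first-class module that regenerates the collection
protocol: walking on even/uneven ground, stairs, slopes, a gravel trail,
a motorcycle ride, two falls from height, four directional stumbles,
progressive and abrupt comas, and free seated rest. The default session
plan lasts 550 s = 5500 samples per participant; a 30-participant cohort
reproduces the 165,000-series scale of the emulated dataset.

Each scenario is an ordered phase list. A phase prescribes an SVMa level
with optional sinusoidal gait oscillation, Gaussian noise, impulsive
surface spikes, or rest "fidgets"; pitch and roll relax toward a per-phase
posture target through a mean-reverting first-order (OU-style) drift. The
acceleration vector is the SVMa magnitude pointed along the gravity
direction implied by the current pitch/roll, so the generated norm matches
the phase profile exactly and orientation carries genuine posture signal.

Key default magnitudes (all engineering choices for class separability —
the protocol reports none; all overridable per phase):

| phenomenon | default |
|---|---|
| rest / stillness | mean 1.0 g, sd 0.02 (rest) / 0.004 (coma still) |
| rest fidgets | +0.1–0.4 g bumps every 5–15 s |
| walking oscillation | 0.3 g at 2 Hz |
| uneven / gravel spikes | 1.5–2.5 g, 0.5–2 s apart |
| stairs steps | 1.8–2.2 g every 0.5 s |
| motorcycle | broadband sd 0.12 + 2.5–3.5 g bumps |
| fall | free-fall 0.15 g for 0.3–0.8 s, impact 4–6 g for 0.1–0.2 s |
| stumble | dip 0.5 g for 0.2–0.4 s, impact 2–3.5 g; labelled span 2–3 s |

Fall labels span the free-fall and impact phases; the post-impact lying
phase is labelled safe (its sd, 0.012, sits deliberately between the coma
stillness and rest noise levels). A stumble's labelled span totals a drawn
2.2–2.8 s (dip + impact + unsteady recovery) and is followed by
walking-like safe recovery; stumble direction steers the pitch/roll
excursion (forward/rear → pitch, left/right → roll). Progressive coma is
rest → sit-down transient → ≥30 s motionless (seated posture); abrupt coma
is standing → fall-like collapse → motionless lying, with the collapse
labelled coma. Per-participant jitter scales oscillation and spike
magnitudes by a factor drawn in [0.9, 1.1].

Every simulate call attaches its realized phase plan to the recording —
machine-readable ground truth used by the test oracles and written as a
`.plan.json` sidecar by the CLI, never as part of the CSV format.

What the simulator does **not** emulate: biomechanically realistic limb
dynamics, sensor bias/saturation, inter-subject gait variability beyond a
scalar magnitude factor, or genuinely ambiguous boundary cases (e.g.
kneeling-first stumbles). Detector comparisons on this data therefore show
that the pipeline reproduces the documented confusability *structure*
(impact-like spikes on rough terrain, rest/coma similarity), not
field-grade accuracy; absolute sensitivities here are higher than any
real deployment would achieve.

## Hierarchical-threshold baseline

The baseline's published description is only "SVM and vertical
acceleration algorithms combined with hierarchical thresholds"; its exact
thresholds are in an earlier system paper and unavailable, so the detector
is a reconstruction with all thresholds calibrated, none hard-coded. Per
sample, in fixed order (fall shadows stumble shadows coma):

1. **fall** — SVMa dipped below `theta_freefall` within the trailing
   `horizon` (1.5 s), the current sample shows impact evidence
   (SVMa > `theta_impact` or |vertical axis| > `theta_vert`), and SVMo
   ranges more than `posture_change` within ±horizon;
2. **stumble** — impact evidence or ΔSVMa > `theta_delta`, without the
   full fall signature;
3. **coma** — rolling SVMa standard deviation over `stillness_duration`
   (5 s) below `stillness_sd`, gated on SVMo > `posture_gate` (15°) so an
   upright motionless stream is not a coma;
4. **safe** otherwise.

The stillness rule and posture gate are inferred from the documented
failure modes (coma alarms during rest; no alarms while standing still).
Calibration is an exhaustive grid search (default 96 configurations over
`theta_freefall`, `theta_impact`, `theta_delta`, `theta_vert`,
`stillness_sd`, `posture_change`) maximizing macro-F1 of the per-sample
labels on the training participants, with deterministic first-in-grid
tie-breaking. "Vertical" is the body axis closest to gravity at rest (z by
default).

## GRU classifier

No deep-learning framework is part of this package's dependency set; the
GRU — forward pass, backpropagation through time, Adam, inverted dropout —
is implemented directly in NumPy and verified against finite-difference
gradients and a closed-form parameter-count formula in the test suite.

Architecture: one GRU layer (64 units; update-gate convention
`h_t = z·h_{t-1} + (1−z)·n_t`) over the window timesteps, then five dense
ReLU layers (128, 64, 32, 16, 8) with dropout 0.2 after the 1st and 3rd,
then a 4-way softmax. Where the recurrent computation sits relative to the
"five hidden layers" is undocumented; placing one GRU layer before the
dense stack is this package's choice. Channels are standardized with
mean/sd estimated from the training tensor. Training uses minibatch Adam
(lr 1e-3), cross-entropy, a seeded 10% validation split for the history
curves, and optional inverse-frequency class weights. All randomness
derives from a single config seed, making (seed, data, config) fully
reproducible on one platform.

The default epoch budget is 10 (batch 64): at cohort scale the NumPy
implementation trains in roughly 10–20 s per epoch on one CPU, and the
simulated classes separate within a few epochs, so a longer schedule buys
nothing here. The `run_comparison` pipeline overrides to 8 epochs,
batch 256 and class weighting on: the cohort is ~90 % safe samples and
fall windows are ~0.3 % of the training set, which plain unweighted
cross-entropy need not discover on a short schedule.

## Evaluation

Per-window: k×k confusion matrix (rows = truth) and one-vs-rest
accuracy `(TP+TN)/total`, precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
specificity `TN/(TN+FP)` and F1 (harmonic mean; 0 when precision and
recall are both 0; zero-denominator ratios reported as 0). The
row-normalized "accuracy percentage" of a confusion display is recall and
is computed as such. Alarm-centric rates (correct/alarms,
incorrect/alarms) deliberately ignore the dominant safe class; zero alarms
raises a typed error rather than returning 0.

Event level: maximal runs of identical non-safe window labels become
alarm events; same-type runs separated by ≤2 s merge. A truth event is
accurately detected when a same-type alarm overlaps it within ±2 s
(both tolerances configurable). Alarms pair one-to-one with truth events
by **maximum bipartite matching per type** (Kuhn's algorithm) — this makes
the accurate-detection count well-defined when one alarm spans two truth
events, and order-invariant; a simpler first-overlap greedy rule is
provably suboptimal exactly there. Unmatched alarms are false alarms of
their emitted type: a cross-type detection (stumble alarm during a true
fall) is a miss for the truth type plus a false alarm of the alarm type,
and is additionally tallied in an event-confusion table.

The coma persistence filter implements the long-horizon disambiguation of
coma vs rest: a coma label stands only if at least `min_fraction`
(default 0.9) of the trailing `horizon` (default 30) labels are coma;
genuine unconsciousness produces an unbroken label series, while a resting
person's fidgets break it. The filter only ever demotes, so it cannot
increase coma false alarms.

## Numerical and design notes

* Sigmoid pre-activations are clipped at ±60 to avoid overflow; softmax is
  computed with max-subtraction; log-probabilities are floored at 1e-12.
* Rolling standard deviation uses cumulative sums over the trailing
  window; positions with an incomplete window report +inf (never "still").
* CSV serialization keeps 5 decimals for acceleration (round-trip error
  < 1e-4 g) and 3 for angles; timestamps are split into ISO date and time
  columns at 0.1 s resolution and merged to seconds-since-start on read.
* The magnetometer named once in the emulated system's description is
  absent from its record schema and never used; it is excluded from the
  data model.
* Degenerate inputs: recordings shorter than one window yield zero
  windows; an empty label series, an off-grid or non-monotone timestamp,
  and an unknown label code raise typed validation errors naming the
  offending line or sample.

## Problem sizes used by the shipped runs

The comparison pipeline and acceptance script use the default
30-participant cohort (165,000 samples), a 25/5 participant split,
training windows at stride 2 (~68,500) and test windows at stride 1
(~27,400); the scenario false-alarm probe uses three 120 s runs per
scenario kind at fixed seeds. The whole acceptance script completes in
about a minute on one CPU.

## Known limitations

* All simulator magnitudes are package defaults, not measured values; the
  event sensitivities obtained on simulated cohorts should not be read as
  estimates of field performance.
* The threshold hierarchy is a reconstruction; the original system's
  portent categories (heavy footsteps, sudden swaying, …) and multi-sensor
  fusion are out of scope.
* The GRU is intentionally small and CPU-bound; no hyperparameter search
  is performed.
* Event-level ground truth is derived from per-window labels, so truth
  events inherit the window labelling convention (a truth event's
  boundaries are window centre times, not raw phase boundaries).
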