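# falldetect

Detection of common construction-worker accidents — **falls from height**,
ground-level **stumbles**, and **comas** (prolonged stillness after a
collapse) — from the 10 Hz stream of a single waist-worn IMU (3-axis
acceleration in g, pitch and roll in degrees).

Threshold detectors tuned in the laboratory are notorious for false alarms
in the field: uneven ground, gravel, stairs and motorcycle rides all
produce impact-like acceleration spikes, and quiet seated rest looks like a
coma. This package implements and compares two detectors under exactly
those confounds:

* **GRU-S** — a gated-recurrent-unit sequence classifier over sliding
  2 s feature windows (implemented from scratch in NumPy, including
  backpropagation through time);
* **HER-S** — a hierarchical-threshold baseline combining
  signal-vector-magnitude and vertical-acceleration rules, with thresholds
  calibrated by grid search.

Because the study data this emulates were destroyed under IRB consent, the
package ships a **scenario simulator** that generates labelled synthetic
cohorts with the documented signal morphology (free-fall dip → impact peak
→ stillness for falls; a 2–3 s dip-peak-recovery for stumbles; fidgeting
rest vs motionless coma; spiky uneven-surface walking).

## The signals and the model

For acceleration `(ax, ay, az)` and orientation `(pitch, roll)`:

* `SVMa = sqrt(ax² + ay² + az²)` — ≈1 g at rest, →0 in free fall, ≫1 g at
  impact;
* `ΔSVMa(t) = SVMa(t) − SVMa(t−1)` — large for abrupt movement;
* `SVMo = sqrt(pitch² + roll²)` — posture change.

Recordings are cut into 20-sample (2 s) windows advanced one sample at a
time; each window takes the status label of its 10th sample
(0 safe, 1 fall, 2 stumble, 3 coma). GRU-S reads the per-timestep channel
set `(ax, ay, az, pitch, roll, SVMa, ΔSVMa, SVMo)` through one GRU layer,
five ReLU dense layers with two dropout layers, and a softmax over the four
classes. HER-S labels each sample by a fixed rule hierarchy:
fall (dip-then-impact with posture change) ≻ stumble (impact or ΔSVMa
spike) ≻ coma (low rolling SVMa variance in a non-upright posture) ≻ safe.

Evaluation is two-level: per-window confusion metrics (accuracy, precision,
recall, specificity, F1, one-vs-rest), and event-level accounting in which
runs of identical non-safe window labels become alarm events that are
matched one-to-one against ground-truth events — yielding per-type
sensitivity (% of true events detected) and false-alarm counts.

## Worked example

```python
import falldetect as fd

rec = fd.simulate_fall(rng_seed=1)          # 11 s fall-from-height scenario
s = fd.svma(rec.ax, rec.ay, rec.az)
for p in rec.phases:                        # ground-truth phase plan
    seg = s[p.start:p.stop]
    print(p.name, p.label.label_name, round(seg.min(), 2), round(seg.max(), 2))
```

prints

```
sway safe 0.84 1.17
freefall fall 0.1 0.18
impact fall 4.4 4.65
still_lying safe 0.97 1.03
```

— the fall signature: SVMa near 1 g while swaying, a dip to ~0.1 g during
free fall, a 4–6 g impact spike, then motionless lying. Running the full
comparison on a simulated 30-participant cohort (25 train / 5 test):

```python
from falldetect.pipeline import run_comparison, format_event_table
res = run_comparison(n_participants=30, n_train=25, seed=1)
print(format_event_table({"GRU": res.gru_events, "Hierarchical": res.her_events}))
```

```
model         index                            fall  stumble     coma
GRU           number of target events            10       20       10
              number of accurate detection       10       20       10
              sensitivity (%)                  100%     100%     100%
              number of false alarms              0        9       17
Hierarchical  number of target events            10       20       10
              number of accurate detection       10       20       10
              sensitivity (%)                  100%     100%     100%
              number of false alarms              5      173        0
```

(your false-alarm counts will vary slightly with the seed): the sequence
model matches the baseline's event sensitivity while cutting fall/stumble
false alarms by an order of magnitude, and the baseline's false alarms
concentrate on uneven ground and motorcycle riding
(`res.scenario_alarms`), not on even walking.

## Command line

```sh
falldetect simulate -n 30 -s 1 -o cohort/          # CSV logs + phase plans
falldetect train --data cohort/ --out model.npz
falldetect detect --model gru --in cohort/P29.csv --model-file model.npz -o pred.csv
falldetect detect --model hier --in cohort/P29.csv -o pred_hier.csv
falldetect evaluate --pred pred.csv -o eval/
falldetect compare -n 30 -s 1 -o comparison/
```

The CSV interchange format is
`date,time,ax,ay,az,pitch,roll,label[,annotation]`; every command writes a
resolved `run_config.yaml` beside its outputs.

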