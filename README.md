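# thermoaffect

Estimation of affective states from facial infrared thermography.

Peripheral vasoconstriction driven by the sympathetic branch of the
autonomic nervous system (ANS) cools the nose tip within seconds, while
the glabella (the skin between the eyebrows) stays comparatively
stable.  `thermoaffect` turns that physiology into a real-time
affective-state monitor of the kind used to track patients during
robot-administered cognitive testing:

* **Imaging** — 68-point facial landmarks tracked in a visible-light
  camera are projected into the 10 Hz, 320 × 256 px thermal frame
  through a planar homography fitted from calibration correspondences;
  polygonal nose-tip and glabella ROIs are rasterized (even-odd rule on
  pixel centers) and averaged into 1-D count signals.
* **Valence** — overlapping 20 s windows of the nose-tip signal
  (stride 2 s) are summarized by eleven features (means of window
  thirds, Shannon entropy, 95th/5th percentile ratio, first- and
  second-order OLS fit coefficients, and the 0.04–0.15 Hz / 0.15–0.4 Hz
  spectral power ratio) and classified by a linear soft-margin SVM as
  *sympathetic* (negative valence) or *parasympathetic* (positive
  valence), with *NA* when a window has insufficient data.
* **Arousal** — the nose-minus-glabella difference signal is
  z-normalized per 8 s window (stride 1 s); the OLS slope *b* of the
  window is thresholded into high (*b* ≤ t_high), medium
  (t_high < *b* ≤ t_low), or low arousal, with the cut points
  calibrated as percentiles of a baseline slope distribution.
* **Fusion** — each 2 s valence emission is paired with the most
  recent arousal emission, tiling Russell's circumplex into six states:
  excited, tense, focused, cautious, calm, bored.
* **Events** — the 10 s after every question is split into five 2 s
  segments; per participant, the normalized fractions of sympathetic
  and parasympathetic emissions per segment are averaged over
  questions and compared by a paired two-sided Student's *t*-test
  across participants.
* **Simulator** — no recordings ship with the published system, so a
  synthetic-data module generates thermal series (and optionally full
  IR frame stacks with landmark tracks) with baseline drift,
  sympathetic cooling / parasympathetic rewarming episodes, sensor
  noise, question schedules, and deterministic ground truth.

## Worked example

```python
import thermoaffect as ta

config = ta.SimConfig(seed=7, duration=300.0)
nose, glabella, truth, _ = ta.simulate_recording(config)
model = ta.train_default_model(seed=11)
result = ta.run_pipeline(nose, glabella, ta.PipelineConfig(seed=7), model)

print(f"valence emissions: {len(result.valence)}  arousal emissions: {len(result.arousal)}")
print(f"arousal thresholds: t_high={result.thresholds.t_high:+.3f}  t_low={result.thresholds.t_low:+.3f} 1/s")
print("state occurrence (% of non-NA emissions):")
for state, pct in result.occurrence.percentages.items():
    print(f"  {state:8s} {pct:6.2f}")
share = ta.aggregate_occurrence(result.occurrence, {"medium", "high"}, {"positive", "negative"})
print(f"medium-or-high arousal share: {share:.2f}%")
```

prints

```
valence emissions: 141  arousal emissions: 293
arousal thresholds: t_high=-0.294  t_low=-0.027 1/s
state occurrence (% of non-NA emissions):
  excited    0.00
  tense     11.35
  focused    7.80
  cautious  32.62
  calm      39.01
  bored      9.22
medium-or-high arousal share: 51.77%
```

A 300 s recording yields 141 valence emissions (one per 2 s window end
from t = 20 s) and 293 arousal emissions (one per second from t = 8 s).
The thresholds are the 10th and 50th percentiles of the recording's own
slope distribution, in units of 1/s on the z-normalized difference
signal.  The occurrence table is the share of each circumplex state
among the non-NA fused emissions, and the final line sums the cells
with medium or high arousal.

The same pipeline is scriptable from the shell:

```sh
thermoaffect simulate --out sim --seed 7 --duration 180 --questions 5
thermoaffect train-valence --out model.json --seed 11
thermoaffect run --nose sim/nose.csv --glabella sim/glabella.csv \
    --model model.json --events sim/events.csv --out out
```

which writes the valence/arousal/state streams, the occurrence table,
the post-question segment statistics and a manifest (every output file
carries the configuration hash).

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
what the simulator does and does not emulate, and known limitations.
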