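# hippogait

Footfall-pattern and stride-parameter analysis for quadrupedal terrestrial
locomotion, built around the gait of the common hippopotamus
(*Hippopotamus amphibius*).

Hippos are among the heaviest land mammals, and how such giants move —
whether they only trot, whether they ever leave the ground entirely —
is measurable from nothing more than the times each foot hits and leaves
the ground in ordinary video. `hippogait` turns tables of those timed foot
contacts into the standard kinematic description of symmetrical quadruped
gaits and the statistics built on it. It is aimed at comparative
biomechanists and veterinary researchers working from video-derived
footfall timings.

## What it computes

From foot-on/foot-off times per limb (LH, LF, RH, RF):

- **Stride parameters** — strides are cut at successive left-hind (LH)
  footfalls; each limb's *phase* φᵢ ∈ [0, 1) is its foot-on as a fraction
  of the stride after the LH contact; *duty factor* DF = stance duration /
  stride duration; *stride frequency* SF = 1/stride duration. Trial means
  average phases circularly.
- **Gait classification** — the forelimb lag (circular mean of the LH→LF
  and RH→RF offsets) is binned into the eight primary footfall patterns
  (trot, pace, lateral/diagonal sequence with singlefoot and couplet
  varieties; 0.125-wide bins) and the pragmatic four-pattern scheme
  (0.25-wide bins); DF ≥ 0.5 is walking, DF < 0.5 running; hind lag
  outside 0.5 ± 0.125 flags asymmetry.
- **Aerial (suspended) phases** — exactly, from the support timeline that
  places each limb's contact interval [φᵢ, φᵢ + DFᵢ) on the unit stride
  circle (zero-support intervals are aerial); and by the simplified
  mean-value criterion: an aerial phase is predicted when DF is below the
  greatest phase gap between consecutive ipsilateral footfalls.
- **Peak limb force** — idealising vertical force over stance as half a
  cosine cycle, a limb carrying a fraction *s* of body weight averaged
  over the stride peaks at *s* · (π/2) / DF body weights.
- **Cross-trial trends** — OLS regression of SF on DF, power-law fits
  (nonlinear least squares, log–log cross-check) of stance and swing
  durations on DF, a Wilcoxon matched-pairs signed-rank comparison of
  fore vs hind duty factors (exact tie-aware enumeration up to 20 pairs),
  and the binned DF frequency distribution with empty-range detection.
- **Synthetic data** — a seeded generator of footfall event streams from
  gait templates with phase/DF jitter and video frame-rate quantization,
  plus a study-level generator that emulates a full survey (46 trials,
  32 individuals, ~169 strides, bimodal DF distribution) so the entire
  pipeline is testable end to end without any downloads.

## Worked example

`examples/02_aerial_prediction_and_loading.py` evaluates the observed
hippo trot mean phases (LF 0.46, RH 0.51, RF 0.94):

```
ipsilateral gaps: left pair 0.54, right pair 0.43 -> max 0.54

DF    predicted aerial   exact aerial fraction
0.36      True             0.170
0.45      True             0.010
0.50      True             0.000
0.60      False            0.000
0.76      False            0.000

half-cosine peak vertical GRF of one forelimb (30% of body weight
per forelimb averaged over the stride):
  DF 0.37: 1.27 body weights
  DF 0.50: 0.94 body weights
  DF 0.75: 0.63 body weights
```

Reading this: with these phases, consecutive footfalls on the left side
are 0.54 of a stride apart, so whenever the mean duty factor drops below
~0.54 the simplified criterion predicts a whole-body aerial phase; the
exact support-timeline computation shows the airborne fraction growing as
DF falls (and disagreeing with the simplified criterion right around
DF ≈ 0.5, where the phase layout matters). At the lowest duty factor a
forelimb's vertical force peaks at about 1.27 body weights.

The other examples analyze a single synthetic trial
(`01_single_trial_analysis.py`) and regenerate a whole survey and its
trend statistics (`03_study_emulation.py`).

A thin CLI wraps the same functions:

```bash
hippogait simulate --study --seed 1 --out events.csv
hippogait analyze events.csv --strides-out strides.csv --trials-out trials.csv
hippogait fit trials.csv --y sf_hz --model linear
```

## Layout

- `src/hippogait/events.py` — footfall data model and events CSV I/O
- `src/hippogait/kinematics.py` — stride segmentation, phases, DF, SF
- `src/hippogait/gaits.py` — classification, support timeline, aerial detection
- `src/hippogait/loading.py` — half-cosine peak-force model
- `src/hippogait/trends.py` — regressions, signed-rank test, DF histogram
- `src/hippogait/simulate.py` — synthetic trial and study generators
- `src/hippogait/pipeline.py` — dataset → stride/trial tables
- `docs/methods.md` — models, assumptions, parameter choices, limitations
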