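# swilift

Analysis toolkit for paired real-vs-virtual object-lifting experiments on
the **size–weight illusion (SWI)**: the robust perceptual effect whereby
the smaller of two equally heavy objects feels heavier, driven by prior
expectations that larger objects weigh more. Studies comparing lifting in
physical reality with a head-mounted-display environment use the SWI to ask
whether those priors operate differently when the visual world is virtual.

`swilift` covers the full chain such a study needs:

* **Synthetic study generation** — heaviness ratings, 90 Hz wrist/object
  tracker streams, and six-item presence questionnaires for a
  within-subjects design (2 object sizes × 2 masses × real/virtual, 5
  washout + 32 test lifts per condition block, counterbalanced order), so
  every downstream stage is testable without access to any deposited data.
* **Reach/lift kinematics** — dual-pass zero-phase 10 Hz Butterworth
  smoothing, velocity by numerical differentiation, threshold-based phase
  segmentation (50 mm/s for 3 consecutive frames), and peak-velocity
  metrics: maximum reach velocity (MRV), maximum lift velocity (MLV), and
  their timing as a percentage of movement time.
* **Scoring** — per-participant z-scored ratings; the regression-based
  illusion index; the presence score (count of the six 1–7 items answered
  6 or 7).
* **Statistics** — z-threshold winsorisation, paired *t* tests with
  Cohen's *d*<sub>z</sub> and 95% CIs, Wilcoxon signed-rank with a
  Shapiro–Wilk gate, 2×2×2 within-subjects ANOVA with partial η²,
  simple regression with *R*², default Jeffreys–Zellner–Siow (JZS) Bayes
  factors, and a-priori power analysis for paired designs.

## The SWI score

For each participant and condition, raw heaviness ratings from the 32 test
lifts are regressed onto lifted object mass (g) and object volume (cm³):

```
rating = b0 + bW · mass + bV · volume + ε        SWI = −(bV / bW)  [g/cm³]
```

The score is the grams of perceived weight change produced by one cm³ of
volume change, sign-flipped so a larger score means a larger illusion. It
is invariant to each participant's private rating scale (any positive
affine rescaling cancels in the ratio), which is what makes open-scale
absolute magnitude estimation usable across participants.

For a paired statistic *t* on *n* participants, the JZS Bayes factor places
a Cauchy(0, 0.707) prior on the standardised effect δ and integrates the
noncentral-*t* likelihood over it by adaptive quadrature; the regression
Bayes factor uses the Zellner–Siow mixture-of-*g* prior (scale √2/4).

## Worked example

```python
from swilift import StudyConfig, run_pipeline, summarize_report

report = run_pipeline(StudyConfig(n_participants=25, seed=1))
print(summarize_report(report))
```

```
SWI real-virtual: mean diff = 0.005 g/cm^3, t(24) = 0.32, p = 0.749, d_z = 0.06, BF10 = 0.22
mrv_m_s: mean diff = 0.111, t(24) = 7.05, p = 0.000, BF10 = 59581.13
t_mrv_pct: mean diff = -0.195, t(24) = -2.13, p = 0.044, BF10 = 1.42
mlv_m_s: mean diff = -0.000, t(24) = -0.46, p = 0.649, BF10 = 0.23
t_mlv_pct: mean diff = 0.050, t(24) = 0.09, p = 0.933, BF10 = 0.21
presence -> virtual SWI: slope = -0.0192, F(1, 23) = 10.52, p = 0.004, R^2 = 0.31, BF10 = 11.16
```

Reading this: both conditions show a solid illusion (generative truth
0.20 g/cm³) and the real−virtual SWI difference is small against its
between-participant spread; reaches are about 0.11 m/s faster in the real
condition (the generator builds in slower, more guarded reaching under the
headset) while lift kinematics do not differ; and participants reporting
more presence show a smaller illusion in the virtual condition.

The same stages are available from the shell:

```bash
swilift simulate --seed 1 --n-participants 25 --out data/
swilift kinematics --streams data/streams.csv --out data/metrics.csv
swilift score --ratings data/ratings.csv --presence data/presence.csv --out data/
swilift analyze --ratings data/ratings.csv --presence data/presence.csv \
                --metrics data/metrics.csv --out data/report.json
swilift validate --ratings data/ratings.csv   # schema/trial-count checks
swilift run --seed 1 --out data/              # everything at once
```

### File formats

* `ratings.csv`: `participant_id, condition (real|virtual), trial_index,
  phase (washout|test), object, rating`
* `streams.csv`: `trial_id, time_s, wrist_x_mm, wrist_y_mm, wrist_z_mm,
  obj_x_mm, obj_y_mm, obj_z_mm` (trial_id encodes participant, condition
  and trial index, e.g. `p07_virtual_12`)
* `presence.csv`: `participant_id, item1..item6` (integers 1–7)
* `metrics.csv`: `trial_id, mrv_mm_s, t_mrv_pct, mlv_mm_s, t_mlv_pct,
  valid, failure_reason`

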