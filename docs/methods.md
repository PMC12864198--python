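# Methods

This note documents the models and numerical choices behind `swilift`: what
the synthetic-data generator emulates, how the kinematic and scoring
pipelines are defined, and how the statistical machinery is computed.

## Study design emulated by the generator

The generator produces a within-subjects lifting experiment: each
participant lifts four black cylinders — a full 2×2 cross of diameter
(5 cm / 10 cm) and cylinder mass (355 g / 490 g), all 7.5 cm tall — in two
conditions, physical reality and a visually matched virtual environment.
A 75 g position tracker is screwed to each object's base in both
conditions, so the lifted masses are 430 g and 565 g; object *volume*
excludes the tracker because visual size cues come from the cylinder.
Each condition block opens with five washout lifts of an intermediate
7.5 cm / 490 g cylinder and continues with 32 test lifts (8 per object) in
one of four fixed pseudo-random orders, assigned cyclically by participant;
no object appears more than twice in a row. Condition order is
counterbalanced (odd participant ids lift real-first). Default sample
size: 25 participants.

## Rating model

Ratings are generated by the same linear form the analysis later fits,

    rating = b0_i + bW_i · mass + bV_ic · volume + N(0, σ_e),

with participant coefficients drawn once per participant (between-subject
SDs on b0, bW, bV) and a participant-by-condition perturbation of the
volume slope bV. This choice is deliberate: the analysis identifies only
the two linear slopes, so a generative model of the same form makes
recovery exact in the noise-free limit — `SWI = −bV/bW` is recovered to
machine precision when all SDs are zero — and lets calibrated effects be
injected directly through the bV condition offsets.

Defaults (units: ratings are an arbitrary open magnitude scale):

| parameter | default | meaning |
|---|---|---|
| beta0_mean / sd | 20 / 5 | baseline rating |
| betaW_mean / sd | 0.1 / 0.005 | rating per gram of lifted mass |
| betaV_mean / sd | −0.02 / 0.002 | rating per cm³ of volume |
| betaV_condition_sd | 0.0079 | participant×condition scatter of bV |
| residual_sd | 3 | trial noise |
| condition_deltas | {real: 0, virtual: 0} | bV mean shift per condition |

These imply a generative illusion strength of −(−0.02)/0.1 = **0.20 g/cm³**
in both conditions. The condition scatter 0.0079 was solved (against a
large independent simulation) so that when a real-minus-virtual difference
of 0.05 g/cm³ is injected (`condition_deltas = {virtual: +0.005}`), the
population standardised effect of the paired contrast is d_z = 0.42 at
n = 25 — a small-to-moderate condition effect against which the paired
test's power can be checked analytically. Ratings are floored at 10⁻⁶ to
respect the positive open scale. Mass enters generation and regression as
*lifted* mass (430/565 g); in a two-level design the slope depends only on
the 135 g contrast, so this choice moves intercepts, never the SWI score.

## Trajectory model

Wrist and object positions are simulated at 90 Hz. The reach is a
minimum-jerk displacement x(τ) = A(10τ³ − 15τ⁴ + 6τ⁵) over amplitude
A = 300 mm, whose peak speed is 1.875·A/T at 50% of movement time — the
standard smooth point-to-point model, and the property the segmentation
tests lean on. The trial timeline is: 0.3 s still, reach, 0.4 s grasp
dwell, a 0.5 s minimum-jerk lift of wrist and object together through
100 mm, a 2 s hold, a 0.5 s lower, 0.3 s still. The object is stationary
until lift onset. Isotropic Gaussian jitter (0.3 mm SD, the order of
consumer tracker noise) is added per axis.

Reach duration is 0.75 s in the real condition and 0.865 s in the virtual
condition, making the peak reach velocities differ by ≈ 0.10 m/s —
emulating the slower, more guarded reaching repeatedly observed under
head-mounted displays. Participants get a shared tempo offset (SD 0.05 s),
a participant-by-condition offset (SD 0.067 s, sized so the MRV contrast
has d_z ≈ 1.2), and per-trial jitter (SD 0.03 s). Lift kinematics are
identical across conditions by construction (a true null).

What the generator does **not** emulate: grip/load forces, corrective
sub-movements, tracker dropouts, drift or occlusion artefacts, rating
drift over trials, and order/learning effects. Passing tests therefore
show the pipeline is correct under clean, well-behaved signals; they do
not show robustness to the messiness of real tracker data beyond the
injected Gaussian jitter.

## Presence model

Each participant has a latent presence level on the 1–7 item scale
(mean 5, SD 1); the six questionnaire items are latent + N(0, 0.8) rounded
into 1..7, and the presence score counts items ≥ 6. The latent level is
linearly coupled to the participant's realised virtual-condition bV
(default slope 0.55 latent units per SD of bV), producing the moderate
*negative* presence→SWI relation (typical R² ≈ 0.2) that motivates the
regression stage; set the slope to 0 for independence.

## Kinematic pipeline

* **Filtering**: 2nd-order Butterworth per pass, 10 Hz cutoff, applied
  forward then backward (zero net phase; 4th-order-equivalent magnitude).
  No cutoff correction is applied for the double pass. Edges are padded by
  reflection, pad length 3× the per-pass order. All six position axes are
  filtered before differentiation.
* **Differentiation**: central differences in the interior, one-sided at
  the edges; speed is the 3-D resultant (Euclidean norm). Resultant speed
  is also what the thresholds act on (a per-axis option exists at ingest
  via the column mapping).
* **Reach segmentation**: onset at the start of the first run of ≥ 3
  samples strictly above 50 mm/s; offset at the start of the first run of
  ≥ 3 samples strictly below 50 mm/s after the onset.
* **Lift segmentation**: onset at the later of the hand's and the object's
  first above-threshold run starts (searched from the reach offset in the
  full pipeline, so the reach itself cannot trigger it); end at the first
  index of maximum object height at or after onset.
* **Metrics**: MRV/MLV are window maxima (earliest index on ties); their
  timings are percentages of the segmented phase duration. Trials that
  never satisfy a rule are flagged with a reason (`no_reach_onset`,
  `no_lift_onset`, …), excluded from condition means, and counted in the
  report — they never raise mid-batch.

Because the lift onset requires the object to exceed 50 mm/s, the lift
"movement time" starts a few samples after true motion onset; peak lift
velocity therefore lands near 45% rather than exactly 50% of the
segmented window even for a perfect minimum-jerk lift. The reach window is
symmetric around its peak, so t_MRV stays at 50%.

## Scoring

* **z-scored ratings**: per participant, test trials pooled across *both*
  conditions (sample SD). Pooling is essential: z-scoring within condition
  would annihilate the condition main effect the ANOVA tests. Washouts are
  excluded everywhere.
* **SWI score**: OLS of raw ratings on lifted mass and volume per
  participant × condition, then −(bV/bW). In the balanced two-level design
  the slopes equal cell-mean difference quotients, which is the
  independent oracle used in tests.
* **Presence score**: count of the six items in {6, 7}; range 0–6.

## Statistics

* **Winsorisation**: values beyond 3.29 sample SDs from the mean (both
  taken from the original vector, single pass) are replaced by the
  boundary. Applied per variable within condition to the participant-level
  condition means before contrasts; zero-variance input passes through
  with a log note. Groups smaller than 3 are left untouched.
* **Paired contrasts**: two-tailed paired t with Cohen's d_z = mean/SD of
  differences (≡ t/√n) and a t-quantile 95% CI. The kinematic contrasts
  are routed by a Shapiro–Wilk gate (α = 0.05) to the Wilcoxon signed-rank
  test when differences look non-normal; the SWI contrast uses the paired
  t directly. Wilcoxon V is the positive-rank sum (average ranks on ties,
  zeros dropped); p is exact for tie-free n ≤ 25, else a
  continuity-corrected normal approximation.
* **ANOVA**: trial-level z-scores are aggregated to participant cell means
  and analysed as a 2 (size) × 2 (weight) × 2 (condition) within-subjects
  ANOVA, each effect tested against its participant-by-effect stratum
  (statsmodels `AnovaRM`); partial η² = F·df_num/(F·df_num + df_den).
  With 2-level factors every effect has 1 numerator df and n−1 denominator
  df, and equals the squared paired t on its contrast scores — the oracle
  the tests check against.
* **JZS Bayes factors**: the paired-design BF10 integrates the
  noncentral-t likelihood over δ ~ Cauchy(0, 0.707) by adaptive quadrature
  (relative tolerance 10⁻⁸), with the substitution δ = r·tan(θ) mapping
  the Cauchy tails onto a bounded interval. The regression BF10 uses the
  Zellner–Siow mixture-of-g prior, g ~ InverseGamma(1/2, n·r²/2) with
  r = √2/4 for a continuous covariate, integrated on g/(1+g) ∈ (0, 1).
  Both are validated against brute Monte-Carlo marginal-likelihood
  estimates. ANOVA-term Bayes factors are *not* reimplemented; only a
  clearly-labelled BIC approximation hook (`bic_bf10`) is provided.
* **Power**: exact noncentral-t power, smallest n found by upward search
  from n = 3. No multiple-testing correction anywhere; all p values are
  reported raw, all tests two-tailed.

## Problem sizes and determinism

All randomness flows from a single config seed through fixed per-stage
sub-seeds, so any stage can be regenerated independently and identical
configs produce byte-identical outputs (reports contain no timestamps).
The simulation studies shipped with the package use 200 replicates for
parameter recovery and power checks and 1,000 replicates for type-I-error
checks at n = 25 — sizes at which binomial/Monte-Carlo error is small
relative to the margins being asserted; the injected reach-velocity effect
is verified against its closed-form minimum-jerk value rather than by
replicated stream simulation.

## Known limitations

* The four shipped trial orders are constructed stand-ins satisfying the
  balance and no-triple-repeat constraints, not the original lab orders.
* The regression Bayes factor reproduces the default mixture-of-g prior
  only approximately when fed rounded R² values; treat it as calibrated to
  a few percent.
* `wilcoxon_signed_rank` requires ≥ 5 non-zero differences; smaller
  samples have no usable two-tailed resolution.
* The Shapiro–Wilk gate is a binary router; borderline p values flip the
  test choice, which is inherent to the gated procedure, not to this
  implementation.
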