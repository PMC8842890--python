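# Methods

This note documents the models, numerical choices and calibrations behind
`pendulearn`, and what the synthetic data can and cannot tell you about real
experiments.

## Pendulum dynamics and score

The virtual pendulum has one internal degree of freedom, the angle `theta`
(0 = hanging down, pi = inverted, positive counter-clockwise in the (y, z)
plane with z up). Its dynamics under pivot acceleration `(y_dd, z_dd)` are

    theta_dd = -(1/l) (y_dd cos(theta) + (z_dd + g) sin(theta))
               - c/(m l^2) theta_d

with m = 2.5 kg, l = 0.35 m (0.25 m for the transfer task), c = 0.16
N·m·s/rad, and g set to 25% of earth gravity (9.81 m/s², so g = 2.4525
m/s²); the reduced gravity keeps a heavy — hence haptically salient —
pendulum manageable. The rendered rod force is

    F_rod = m (theta_d^2 l - y_dd sin(theta) + (g + z_dd) cos(theta)),

decomposed onto the hand as `(F_rod sin(theta), -F_rod cos(theta))` under
the convention ball = pivot + l·(sin θ, −cos θ).

Integration is fixed-step classical RK4 with the pivot acceleration held
constant over each sample (zero-order hold), the discrete-time analogue of
a 3 kHz real-time loop; the default integrator step is 1/3000 s with
automatic sub-stepping when the input trajectory is sampled more coarsely.
For this smooth 1-DoF ODE, RK4 at these steps conserves energy to a
relative drift below 1e-6 over 30 s (measured ~1e-12), and convergence is
verified to be 4th order.

The score integrates `k (pi/6 − |theta − pi|)` (k = 19 points·rad⁻¹·s⁻¹,
trapezoidal rule on the wrapped angle distance) over every interval in
which `|theta − pi| < pi/6` and `|theta_d| < pi/3`; an interval starts at
the first sample satisfying both conditions and ends at the first violating
either, and the score is retained across drops within a block. `theta` is
stored unwrapped; the inversion distance uses the wrapped view, so −pi and
+pi are the same inverted pose. Every block starts from `theta = 0,
theta_d = 0` with the score reset. A full 30-s perfect hold is worth
`19·(pi/6)·30 ≈ 298.5` points; because a real block always spends some
seconds swinging up, attainable scores are lower (our best synthetic
participant reaches ≈ 227 with a ~2.6-s swing-up, consistent with a
practical ceiling around 250).

## Arm model

The exoskeleton-supported arm is reduced to a planar two-link chain
(shoulder elevation, elbow flexion) in the task plane — the task and all
metrics live in that plane, so out-of-plane joints add nothing here.
Defaults: segment masses 2.0/1.5 kg, lengths 0.30/0.25 m, COM fractions
0.5, all configurable. The arm is under full earth gravity (unlike the
virtual pendulum).

* Gravity holding torques come from the static moment of each segment's
  weight; weight support returns `−fraction ×` those torques, so 100%
  support cancels the arm's weight at every pose (machine-precision
  cancellation is a test invariant).
* Segment masses are estimated from static torque readings at a calibration
  pose (planar reduction: −10° shoulder elevation, −30° elbow flexion).
  The static model is linear in the two masses, so the estimate is ordinary
  least squares over the recorded window; poses where the two mass columns
  become collinear (e.g. both segments vertical) are rejected as
  rank-deficient. The estimator is exact on noiseless data and unbiased
  under additive zero-mean sensor noise.
* Hand forces map to joint torques via the planar Jacobian transpose. The
  effort bookkeeping sums, per sample: the participant's reaction to the
  rendered rod force (−JᵀF of the force on the hand, when haptics are on),
  minus the robot's support torques (when support is on), plus the gravity
  holding torques. With full support and no haptics the generated torque is
  identically zero — the mechanical reason the weight-supported groups show
  low effort. The model is static: no inertial/Coriolis arm terms, no
  muscle or fatigue model.

## Outcome metrics

Each metric yields one value per block.

* **Movement phase difference.** Pivot horizontal velocity and the ball's
  relative horizontal velocity (`l·theta_d·cos(theta)`, computed
  analytically — exact in simulation) are restricted to the samples before
  the block's first inversion onset (the whole block if never inverted);
  once inverted the motion is a hold, not a cyclic swing. Both series are
  band-passed (2nd-order Butterworth, 0.5–10 Hz) applied forward–backward:
  a phase metric must not inherit the filter's own phase lag, and the
  direction of filtering is a free choice we fix at zero-phase. After
  normalisation to zero mean/unit SD, Hilbert-transform phases are taken
  and the metric is the arithmetic mean of the per-sample wrapped
  difference `phi_pivot − phi_ball` (circular mean available as an option;
  the two agree for the concentrated distributions seen in practice).
  Positive = pivot leads. Windows shorter than 2 s are refused. Recovery of
  imposed offsets (±pi/6 … ±pi/2, 0.6–3 Hz) is verified within ±0.05 rad
  against a cross-spectral oracle, and the metric is insensitive to the
  sampling rate on band-limited signals.
* **Movement variability** is the sample SD of pivot y and z positions;
  **hand speed** (used by the transfer-kinematics analysis) is the mean
  magnitude of the pivot velocity; **physical effort** is the time-average
  Euclidean norm of the generated joint-torque series.

## Synthetic participants

No behavioural model is claimed: the generator's controller is a stand-in
whose purpose is to produce protocol-shaped data with tunable, recoverable
group effects.

The controller combines (i) energy-shaping swing-up,
`u = sat(k_e (E − E_ref) · theta_d cos(theta))` with `E_ref` 5% above the
upright energy so the pendulum arrives slowly enough to be caught — a pure
bang-bang drive on `sign(theta_d cos theta)` overshoots the catch window,
which is why the saturated energy-regulated form is used; (ii) a
near-inversion stabiliser `u = −(g + l·kp)·wrap(theta − pi) − l·kd·theta_d`
(engaged within 0.7 rad and 4 rad/s of the inverted rest state); and
(iii) a weak spring–damper centering the pivot, with a hard ±0.4 m clip as
backstop. Vertical pivot motion is exploration noise around the same kind
of centering.

Sensorimotor imperfection enters in three places, all tied to a scalar
skill in [0, 1]:

* command noise: white acceleration noise with SD
  `motor_noise_sd · (1 − skill)` (quoted at 600 Hz and rescaled by
  `sqrt(fs/600)` so the induced velocity diffusion is rate-invariant);
* drive and stabiliser authority: the pump saturation scales with
  `0.5 + 0.5·skill`, the stabiliser gains with `0.1 + 0.9·skill`, so both
  swing-up speed and hold quality improve with skill;
* timing: the pump's switching signal is read with a delay
  `max(0, feedback_delay − phase_lead/omega_n)`. The phase lead models
  learned anticipation: it can cancel the reaction delay but not act ahead
  of the movement. The stabiliser and the pump's energy level use the
  current state — balancing an unstable equilibrium and perceiving the
  swing amplitude both rest on prediction over slower percepts, and naive
  fully-delayed feedback produced unphysical behaviour (skilled
  participants dropping the pendulum more often than novices).

Skill grows linearly over the 24 training-phase blocks. Group effects add
to the per-block increments depending on the modality experienced in that
block: haptic rendering adds to the skill gain and to the acquired phase
lead; weight support subtracts from both; both raise vertical exploration
noise during the T blocks (a training-modality behaviour — test and
catch-trial blocks, performed in the common modality, are left
unaffected so groups stay comparable at test).

### Population and protocol defaults

Per-participant parameters are drawn once per cohort (counter-based
seeding: participant i uses `SeedSequence(master_seed, spawn_key=(i,))`,
and each block its own child sequence, so participants and blocks are
invariant to cohort size and to which phases are simulated):

| parameter | distribution | rationale |
|---|---|---|
| initial skill | N(0.30, 0.08), clipped to [0.10, 0.55] | novices who can usually swing up within a block |
| learning rate / block | N(0.006, 0.002), clipped to [0, 0.012] | ~0.15 skill gained over 24 blocks; stays in the quasi-linear region of the skill→score map, matching approximately-linear learning curves |
| phase lead | N(0.30, 0.10) rad | partial delay compensation |
| command noise | \|N(2.0, 0.5)\| m/s² | visible motor variability at low skill |
| feedback delay | N(0.15, 0.03) s, clipped to [0.05, 0.25] | visuomotor reaction-time range |

The protocol is fixed: 36 blocks (2 BL, 2 TBL, 24 training with catch
trials at positions 5/9/13/17, 2 STR, 2 TSTR, 2 LTR, 2 TLTR), test blocks
in the visuo-haptic modality, transfer blocks with the 0.25 m rod, 30-s
blocks by default. Replicate-study computations (type-I error, power) run
at a reduced scale — 10-s blocks at 600 Hz, simulating only the phases that
enter the contrast — so that hundreds of full studies remain affordable;
the per-block seeding makes the reduced runs exact subsets of full runs.

### Effect-size calibration

The demonstration configuration injects a haptic-rendering learning benefit
of one within-cell SD: with the population above, the SD of the LTR−BL
score contrast at the replicate scale is ≈ 5 points, and a skill-gain
increment of 0.005/block (plus the small acquired-lead benefit) shifts the
HR groups by the same amount (measured Cohen's d ≈ 1.0). The other
demonstration magnitudes (weight support −0.003/block on learning,
±0.004–0.005 rad/block on acquired lead, +60%/+80% vertical exploration
noise) encode directions only. `GroupEffects.null()` zeroes everything,
making the four groups exchangeable; under the null the factorial
haptic-rendering test on the LTR−BL score contrast rejects at ≈ 0.045–0.05
over 500 replicate studies, and under the demonstration config it detects
the effect in ≈ 85% of replicates (both recomputed by the test suite and
`scripts/acceptance.py`).

### Questionnaires

Agency (−3…3) and four intrinsic-motivation subscales (1…7), three items
each, at three time points (after baseline, after training, after long-term
retention). Items are rounded, clipped Gaussians around high means (agency
1.7, interest/enjoyment 5.6, effort/importance 5.5, pressure/tension 2.5,
perceived competence 4.5; SD 1), with a small per-subscale probability
(default 2%) of one unanswered item — at most one, matching the scoring
rule that averages the remaining two and refuses subscales with two or more
missing items. No group effects are injected by default.

## Statistical pipeline

* **Contrasts.** T−CT (mean of 20 training blocks minus mean of 4 catch
  trials) removes an approximately linear learning trend up to a constant
  factor: under value = s·(training position), T−CT = 1.8·s exactly (mean
  position 12.8 vs 11.0). Retention contrasts average the two blocks at
  each end (STR−BL, LTR−BL; TSTR−TBL and TLTR−TBL for transfer).
* **Factorial tests.** Normality of the contrast values is checked with a
  one-sample KS test on the standardised 2×2 cell residuals at alpha = 0.05
  (the exact KS variant is a free choice; residuals against a fitted normal
  is the one implemented). Normal data: two-way ANOVA via OLS with sum
  coding and type-III sums of squares (identical to type I/II on the
  balanced design); non-normal: two Kruskal–Wallis tests, one per factor,
  no interaction. A constant response returns p = 1 without testing.
  Significant interactions are followed by four Welch-free two-sample
  t-tests (each factor within each level of the other), Bonferroni-adjusted
  by the family size 4.
* **Correlations** are Pearson r between |phase difference| and score, one
  participant-level point per test phase.
* **Learning curves.** `score ~ block` vs `score ~ block + log(block)`
  as Gaussian-identity linear models (the natural reading of a GLM on a
  continuous score), compared with the nested-model F-test on residual sums
  of squares.
* **Transfer kinematics.** Mixed ANOVA (pingouin) with rod length as the
  within-subject factor and training group between, applied to horizontal
  variability and mean hand speed at long-term retention.

The ANOVA engine is verified against an explicit sums-of-squares oracle to
1e-10; the whole pipeline is a pure function of (config, seed) and
reproduces byte-identical output files.

## What the synthetic data do and do not show

Passing tests demonstrate that the simulator obeys its physics, that the
metrics recover known ground truth, and that the statistical machinery has
the nominal operating characteristics on data with the protocol's exact
structure. They do not validate the controller as a model of human motor
learning: its learning curve is linear by construction, its noise is white,
fatigue and muscle dynamics are absent, and the mapping from modality to
behaviour is injected rather than emergent. Two known divergences from
human data: the measured movement phase difference is an emergent, circular
quantity that responds non-monotonically to the latent lead/delay knobs;
and because delayed participants show *larger* measured phase differences,
the |phase|–score correlation tends to come out negative in synthetic
cohorts, whereas human studies report positive correlations at retention.
Conclusions about real cohorts require the real data; the pipeline accepts
them through the same CSV interface.
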