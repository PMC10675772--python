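# Methods

This note records the models, conventions, and numerical choices behind
`gaitbalance`, and what the synthetic experiments do and do not show.

## Balance model

Dynamic balance is described by the inclination angles (IA) of the
COP→COM unit vector **p** against the vertical, split into a sagittal and
a frontal component, and their time derivatives (RCIA).  The lab frame is
right-handed with **X** the direction of progression, **Z** vertical and
**Y = Z × X** pointing to the walker's left.  With **v = Z × p**:
sagittal IA = asin(v·Y), positive when the COM is anterior to the COP;
frontal IA = −asin(v·X) for right stance and +asin(v·X) for left stance,
positive when the COM deviates towards the contralateral limb.  The
left-handed alternative for **Y** would silently flip the frontal sign
convention; the choice here makes the stance-side rule come out as stated.
Arguments of asin are clamped to [−1, 1]; an excess beyond 1e-12 emits a
warning because it indicates an upstream normalization problem rather than
round-off.

The gait cycle runs heel-strike (HS) to ipsilateral heel-strike and is
partitioned by contralateral toe-off (CTO), contralateral heel-strike
(CHS) and toe-off (TO) into initial double-limb support (iDLS), single-limb
support (SLS), terminal double-limb support (tDLS) and swing (SW).

### Ground-truth pipeline

* **Events** are threshold crossings of each plate's vertical force:
  20 N with a 5-sample debounce (both configurable).  The exact rule used
  by laboratory software varies; this is standard force-plate practice and
  the tests only rely on crossings being recovered to ±1 sample.
* **COP** uses the standard plate formulae
  `COP_x = −(M_y + F_x z0)/F_z`, `COP_y = (M_x − F_y z0)/F_z` with the
  surface offset `z0`; samples with `F_z` at or below threshold are masked,
  never divided.  Multi-plate records combine per-plate COPs weighted by
  vertical force.
* **COM** is the mass-weighted sum of segmental COM trajectories (13
  segments in the full model; any k ≥ 1 is accepted).  Mass fractions must
  sum to 1 within 1e-6.
* **RCIA** differentiates a cubic smoothing spline whose smoothing
  parameter is chosen by generalized cross-validation
  (`scipy.interpolate.make_smoothing_spline`, the same GCV criterion as
  the classical GCVSPL routine).  Differentiation happens at the native
  sampling rate, and the derivative curve is then cycle-normalized; the
  alternative order (normalize, then differentiate) differs only through
  interpolation error but would change the units bookkeeping.
* **Cycle normalization** resamples HS→next-HS onto 101 points (0–100 %)
  with a cubic spline for kinematic signals (linear interpolation is
  available for event-like flags).  It is exactly idempotent on
  101-point single-cycle inputs.

## IMU preparation

The six pelvis-IMU channels (3 accelerations, 3 angular rates, 100 Hz) are
filtered with a fourth-order Butterworth low-pass at 15 Hz applied
forward-backward.  Zero-phase filtering is chosen because a one-pass filter
would delay the IMU inputs by several samples relative to the force-plate
derived targets; attenuation checks in the tests use the composed
(squared-magnitude) response.  Channels are scaled to [−1, 1] by
`x → 2(x − min)/(max − min) − 1` with min/max taken over the **training
split only** and frozen; validation/test values may leave [−1, 1] and are
deliberately not clipped.  Cycle normalization of inputs uses the
force-plate events; IMU-only event detection is left as an integration
point since no specific algorithm is prescribed for it.

## Recurrent models

LSTM (gates f, i, o and candidate) and GRU (gates u, r and candidate)
cells are implemented directly from the gate equations, with the GRU
update written as `h ← (1−u)∘h + u∘tanh(W_h[r∘h, x] + b_h)` — the update
gate weights the *new* candidate — and the reset gate applied to the
hidden state *before* the recurrent projection.  Every gate carries dual
bias vectors (input-side and recurrent-side), so a layer with input width
d, hidden size H and G gate blocks holds `G(dH + H² + 2H)` parameters per
direction.  This convention is what reproduces the published totals of the
two recurrent layers at hidden size 512 (uni-LSTM 3.17 M, bi-LSTM 8.43 M,
bi-GRU 6.32 M, 3 significant figures; the uni-GRU total computes to
2.374 M, which rounds to 2.37 M rather than the printed 2.38 M — noted,
not reconciled).  Two architecture profiles are provided: `table5`
(512/512), the default for parameter accounting, and `text` (256/64),
matching the written layer-size description and cheap enough for CPU
training.

A bi-directional layer runs one cell over the sequence and a second cell
over the reversed sequence, concatenating the two hidden states per step,
which doubles the layer's parameters and the next layer's input width.
After the second recurrent layer the per-step outputs are flattened and
passed through a 202-unit tanh dense stage and a 202-unit linear output
stage, reshaped to 2 × 101 (sagittal and frontal IA at every percent of
the cycle).  Whether the original dense stage consumed flattened per-step
outputs or a final hidden state is not derivable from the architecture
description; the flattened readout is used because whole-curve regression
needs per-step information.  Weights initialize uniformly in ±1/√H,
seed-controlled.

Forward and backward passes are hand-written NumPy (float64).  Gradient
correctness is enforced by central-difference checks on small models for
all four architectures and both losses.

## Losses and training

With N = 101 cycle points, the standard loss is the mean squared IA error.
The weighted loss adds λ · mean squared error between the
finite-difference rate of the predicted IA (central differences inside,
one-sided at the ends) and the reference RCIA; λ defaults to 5.  The loss
operates on scaled model outputs; the rate term divides by
`dt = cycle_duration/100` per trial and scales the reference RCIA by the
same output gain, preserving per-second rate semantics across trials of
different durations.  Because RCIA magnitudes (tens to hundreds of °/s)
dwarf IA magnitudes (degrees), λ = 5 makes the rate term dominate; this is
inherent to the formulation and visible in the examples as a small IA
accuracy cost in exchange for much better RCIA accuracy.

Training uses Adam with the reference protocol as defaults (lr 1e-4,
β₁ 0.9, β₂ 0.999, batch 32, ≤100 epochs, 80/10/10 trial-level split,
seed-controlled shuffling) and retains the best-validation parameters
("maximum epochs" is interpreted with best-checkpoint retention, as no
early-stopping rule is prescribed).  Divergence (non-finite loss) aborts
with a diagnostic.

**Scaled-down protocol.**  The test suite trains on small cohorts (12
subjects × 6 cycles), with the `text` profile or smaller hidden sizes
(32/16), 10–25 epochs, and a learning rate of 1e-3 to 3e-3.  A full-scale
run takes ~1300 Adam steps (100 epochs × 13 batches of 416 trials); the
desk-scale runs take ~50–150 steps, and the larger learning rate
compensates for the shorter schedule.  `TrainConfig` defaults remain the
full-scale values.

## Synthetic cohorts

The generator's role is to provide data with the same *statistical
structure* the pipeline assumes, not to imitate real waveforms
sample-by-sample.

* **Base curves** per plane are minimum-bending-energy periodic harmonic
  series (K = 10) constrained to physiological event values and sub-phase
  means (sagittal IA ≈ ±10°, frontal IA ≈ ±5–7°, RCIA in the tens to
  ~150 °/s).  The frontal template additionally pins an early-single-
  support rate dip (−60 °/s at 20 % cycle) so that the CTO rate value is
  an interior point of its windows — a geometric precondition for clean
  effect injection (below).
* **Variability**: each subject perturbs the curves with k = 1..3
  harmonics of fixed amplitude (0.9/0.7/0.5° sagittal, 0.6/0.5/0.3°
  frontal) and uniform-phase Gaussian coefficients; each trial adds 30 %
  of that again plus a cycle-duration jitter (subject ~N(1.1, 0.1²) s,
  trial ±0.02 s, quantized to 10 ms so all sample clocks align).  Cycle
  durations are a convention — no reference values exist for them here.
* **IMU synthesis**: the six channels are a fixed full-rank 6 × 6 mixing
  of [sagittal IA, frontal IA, their rates, two extra harmonics], passed
  through a mild fixed monotone nonlinearity (u + 0.3 tanh u), scaled to
  realistic accelerometer/gyroscope magnitudes (gravity offset on the
  vertical channel) and given white Gaussian noise (defaults 0.1 m/s²,
  1 °/s).  The map is invertible by construction, so the IMU→IA problem is
  solvable and training-convergence tests are meaningful.
* **Effect injection**: a requested effect (variable v, Cohen's d,
  direction) adds to the older group a fixed offset curve computed as the
  minimum-bending-energy harmonic (K = 12) satisfying *hard* constraints
  on the four event values of both quantities plus the targeted
  functionals, and *soft* constraints (weights 1e3 / 1e2) holding the
  sub-phase means and ranges of the non-targeted functionals at their base
  values.  Two structural facts make softness necessary: the discrete
  window means of the rate grid obey an exact identity with its event
  values, and a range cannot be preserved when the targeted event *is* the
  window extreme.  Range rows are relinearized iteratively at the current
  window extrema and evaluated as **expected** ranges under the
  subject-perturbation distribution (fixed-seed Monte Carlo with common
  random numbers), which removes the bias that noise-free compensation
  leaves behind.  The amplitude is `direction · d · σ_v`, with σ_v the
  between-subject SD of variable v estimated by a fixed-seed Monte Carlo
  of the variability model (1200 virtual subjects, including
  trial-averaging).  Default effects: variables 10, 14, 20 at d = 1.58,
  1.39, 0.93, all with the older group lower.
* **Matched groups**: with `matched_groups=True` both groups share the
  same subject-level perturbation draws (a matched-cohort design), so null
  between-group differences are essentially zero while pooled SDs remain
  at full between-subject scale; the independent t-test then flags exactly
  the injected variables.  With the default unmatched sampling, null
  variables reject at the nominal α — both behaviours are tested.
* **Raw trials** (`make_raw_trial`) additionally synthesize 1200 Hz plate
  forces/moments whose 20 N threshold crossings occur at the encoded
  events (an M-shaped stance profile solved for its crossing offset),
  a COP path shared by both plates during double support (so the
  force-weighted net COP equals the template path; individually the plate
  COPs are simplified), 200 Hz COM/segment trajectories that encode the IA
  template exactly, and the 100 Hz IMU record.  Round trips through the
  ground-truth pipeline recover events to ±1 sample and IA to <0.1°.

**What passing tests show, and what they do not.**  The generator shares
the pipeline's structural assumptions (harmonic smoothness, a fixed
invertible IMU↔balance relation, stationary noise).  Tests against it
demonstrate correctness of the implementation and internal consistency of
the statistical machinery — they do not demonstrate that a recurrent model
trained on real IMU data achieves any particular accuracy, because real
soft-tissue artefacts, sensor drift, inter-subject anatomical variation
and non-stationarity are deliberately not modelled.

## Numerical choices and degenerate inputs

* All computation is float64; cell-step equivalence to an element-wise
  oracle is held to 1e-12, gradient checks to 1e-5 (norm-wise).
* Constant channels cannot be scaled and are rejected by name; flat
  ground-truth curves make rRMSE undefined and raise.
* Degenerate zero-variance t-tests return t = 0, p = 1 for equal means and
  ±∞, p = 0 otherwise; the Pearson r of effect sizes is NaN when either
  vector is constant.
* Event values are read at the nearest 1 % grid point (events land on
  integer percents by construction in synthetic cohorts); sub-phase
  windows are inclusive grid slices.
* Effect sizes are reported as absolute pooled-SD Cohen's d; no
  multiple-testing correction is applied across the 48 variables by
  default (matching the reference analysis protocol), with a Bonferroni
  flag available.
* Per-subject variable values average over that subject's trials before
  group inference, consistent with 13 + 13 degrees of freedom.

## Known limitations

* The agreement analysis on a 10 % held-out split leaves only ~2 trials
  per subject; per-subject averages are then noisy, and the `scope="all"`
  evaluation path exists for analyses that need stable subject estimates.
* The injection machinery guarantees leakage below ~0.3 pooled SDs on
  non-targeted variables for the default effect set; extreme effect sizes
  or effects on range-kind variables inherit the physical coupling between
  an extreme point and its window range and may leak more.
* Uni-directional models cannot use future cycle context; their causality
  is tested, but no claim is made about which architecture is superior on
  real data.
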