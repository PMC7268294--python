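# Methods

This note documents the models, processing choices and limitations behind
`splitbelt`: what each stage assumes, which constants matter and why they
have the defaults they do, and what the synthetic-data generator does and
does not emulate.

## Protocol model

A session is a sequence of epochs — optionally a slow baseline (flat
sessions only), a mid-speed baseline, a split-belt adaptation epoch and a
tied-belt post-adaptation epoch.  Belt speeds derive from the subject's
self-selected mid speed: slow = 66.6% and fast = 133.3% of mid, each rounded
to 2 decimals half-away-from-zero (the treadmill display convention).  This
yields a 2:1 split ratio and keeps (slow + fast)/2 equal to mid, so the
average belt speed is constant across epochs.  The paretic leg always walks
on the slow belt; `ProtocolConfig` validates this, along with the speed rule
(explicit speeds deviating by more than 0.01 m/s from the rule are rejected).

Rounding caveat: because a published mid speed is itself a rounded number,
no deterministic rule applied to it can reproduce every published slow/fast
pair; with the rule above, 22 of the 24 reference values match exactly and
two fast speeds differ by 0.01 m/s.  The package treats the rule, not the
printed pairs, as normative.

Default epoch plan: 50 baseline strides per baseline epoch, 600 adaptation
strides, 300 post-adaptation strides — the scale of the reference protocol
(minimums there: 50 / 300 / 10).

## Signal conditioning

* **Frames.** Raw data arrive in the lab frame; all analysis happens in the
  treadmill-surface frame (+x uphill along the belt, +y mediolateral, +z
  surface-normal), reached by rotating positions and force vectors about the
  mediolateral axis by −slope.  Rotations are applied identically to
  kinematics and kinetics and are exactly invertible.
* **Force filtering.** The AP channel is low-passed at 20 Hz with a
  zero-phase (forward–backward) 4th-order Butterworth — the cutoff is the
  protocol constant; the realization is the biomechanics standard choice.
  The normal channel used for event detection is median-filtered with a 5 ms
  centered window (5 samples at 1000 Hz; the window shrinks at the edges).
* **Marker gaps.** Interior occlusion gaps up to a configurable length
  (default 10 frames) are filled per coordinate by an interpolating quintic
  B-spline through up to 10 valid frames on each side.  An interpolating
  (smoothing = 0) spline is assumed; a quintic reproduces quintic
  polynomials exactly, which the tests exploit.  Leading/trailing and
  over-long gaps stay masked; originally valid frames are never altered.
  Near the swing→stance velocity kink a quintic can overshoot by a few mm —
  strides built from filled frames are flagged.

## Events and strides

Heel strikes are threshold crossings of the normal force: 10 N on
median-filtered data offline; a 30 N raw-signal mode emulates the real-time
stride counter (the two agree within ~10 ms on clean data).  Debouncing:
sub-threshold dropouts shorter than `min_swing` (default 100 ms) are merged
into the surrounding stance, then stances shorter than `min_stance`
(default 100 ms) are discarded — both far below physiological stance/swing
durations.  A stride runs between consecutive paretic heel strikes and must
contain exactly one non-paretic strike; malformed intervals are dropped and
counted.  Strides are labeled with the epoch active at their starting heel
strike from the session's belt-speed schedule (`schedule.tsv`); strides
spanning an epoch transition are dropped rather than mixed.  The paretic leg
is the reference leg for stride counting.

## Spatial and kinetic parameters

Force-clock events (1000 Hz) map to the nearest kinematic frame (100 Hz,
≤ 5 ms off).  Step length is the ankle-to-ankle x-distance at the leading
leg's heel strike; the hip reference is the mean x of the two greater
trochanters; α and X follow (positive ahead / negative behind the hips),
with α_lead − X_trail = SL by construction.  SLA normalizes the step-length
difference by stride length, making it dimensionless and robust to body
size; strides with any missing marker are excluded listwise from that
stride's parameters only.

Peak propulsion is the maximum normalized AP force in stance *after the
braking minimum*: anchoring the search at argmin(AP) excludes the initial
positive transient that can follow heel strike without any tunable window
(a first-zero-crossing variant is available via `mode="zero_crossing"`).
If AP never goes negative the stride is flagged atypical and the second
half of stance is searched.  No slope-specific gravity bias is removed from
forces; epoch differencing downstream handles biases.  Propulsion impulse is
exposed as a diagnostic extra.  Each leg's forces come from its own belt's
plate; cross-stepping onto the wrong belt is not detected — a known
limitation.

## Outcome measures

Per parameter: Baseline = mean of the last 40 mid-speed baseline strides;
Late Adaptation = mean(last 40 adaptation) − Baseline; After-Effects =
mean(first 5 post) − Baseline; ΔAdapt = late − early adaptation means;
ΔPost = Baseline − early post (identically −After-Effects; Baseline proxies
late post-adaptation, which is a stated limitation of the design).  Windows
skip missing-flagged strides, extending over the nearest valid strides;
epochs with too few valid strides raise an error naming the epoch.  The
stored values are the literal differences; any "increase in magnitude is
positive" sign convention is left to reporting, so the algebraic invariants
stay checkable.  Raw window means (early/late adaptation, early post, slow
baseline) are stored alongside because the regression analyses need
unbiased positions.  Time courses are published as means of 5 consecutive
strides (trailing partial bins kept and flagged).

## Statistics

* Paired t-tests report the paired Cohen's d as d_z = mean(diff)/sd(diff)
  (d_av would be an alternative; d_z is the default here).
* The repeated-measures ANOVA uses the classical univariate decomposition
  with subjects as a random blocking factor: every within effect is tested
  against its interaction with subjects; in the split-plot (mixed) design
  the between factor is tested against the between-subject residual and
  within effects (and their interactions with the between factor) against
  their interaction with subjects-within-groups.  η² = SS_effect/SS_total.
  The decomposition is verified against an orthogonal-projection oracle and
  third-party implementations in the tests, and must sum to SS_total on
  every call.
* Lilliefors: D against a normal with estimated mean/sd; the p-value is an
  add-one Monte Carlo proportion from Gaussian null samples of the same size
  (seeded, exact for any n; default 10 000 replicates).  Measured type-I
  error at α = 0.05 is ~0.05 with n = 24.  Power caveat: against U(0,1) the
  best-fit normal is only ≈ 0.042 away in sup-norm, so rejection is
  unreliable below n ≈ 150 and near-certain above n ≈ 250.
* Through-origin regression |y| = a|z|: a = Σz′y′/Σz′², se with df = n − 1,
  95% CI from the t distribution, *uncentered* R² = 1 − SSE/Σy′² (the
  appropriate definition without an intercept), plus the centered Pearson r
  of the transformed values as an effect size.  Absolute values prevent the
  positive-α / negative-X clustering from inflating linearity.
* Parametric tests proceed when Lilliefors does not reject; the gate
  decision is logged but no nonparametric fallback is applied.

## Synthetic-data generator

Each gait parameter follows a single exponential per epoch: during
adaptation p(s) = p_ss + (p₀ − p_ss)·e^(−s/τ); during post-adaptation
p(s) = baseline + a₀·e^(−s/τ_w); baselines are stationary; i.i.d. Gaussian
stride-to-stride noise is added per curve.  A single exponential is the
simplest curve consistent with observed adaptation time courses; a
double-exponential can be composed by the caller if needed.  Defaults (mm,
N/kg; τ in strides) encode: a mild baseline step asymmetry, an early
negative SLA perturbation adapting toward symmetry (τ ≈ 30–40), positive
SLA after-effects produced by the ipsilateral-α / swapped-X pattern of
post-adaptation leg orientations, a paretic propulsion deficit, and slope
effects — more propulsion (+0.09 N/kg per degree), more posterior trailing
positions (−3 mm per degree) and larger after-effects on the incline.
Stride-to-stride noise defaults: 8 mm positions, 0.12 N/kg propulsion;
sensor noise: 0.5 mm markers, 2 N forces.

Signal synthesis derives timing from geometry: the interval from one leg's
landing to the contralateral landing is (α − X)/v_belt for the leg on the
ground, so stride durations emerge from the spatial truths and belt speeds
(≈ 1.5 s at 0.7 m/s).  Heel-strike times snap to the 100 Hz marker grid and
ankle trajectories are anchored *exactly* at hip + α at the own heel strike
and hip + X at the contralateral one (linear in stance at ≈ belt speed,
cosine-blend swing).  This makes noise-free full-loop recovery exact, which
is what allows the 2 mm / 0.005-SLA recovery invariants to be meaningful
tests of the extraction chain rather than of marker discretization.  The
normal-force stance template is a two-term sine (double hump, ≈ 1.1 body
weight) plus a fast loading transient so the 10/30 N crossings stay within
~1 ms of the scheduled heel strike at any walking speed; the AP template is
a braking/propulsion biphasic whose positive lobe peaks exactly at the
stride's true propulsion value, plus a small positive post-contact transient
(0.3 N/kg) to exercise the exclusion rule.  Everything is generated in the
surface frame, rotated into the lab frame by the slope, and only then
corrupted with sensor noise.  Resting breaks are zero-force gaps between
epochs (default 5 s); identical seeds give bit-identical output.

What the generator does **not** emulate: muscle dynamics, double-support
force sharing, cross-stepping, marker soft-tissue artifact, belt-speed
fluctuations, handrail loads, or realistic inter-subject waveform variety.
Passing recovery tests therefore demonstrates correctness of the analysis
chain on signals with the assumed structure, not robustness to every
laboratory artifact.

## Validation problem sizes

The recovery harness runs 12 synthetic subjects (the reference cohort's mid
speeds and incline slopes, 70 kg default mass) × 2 sessions at the default
epoch plan, noise-free, plus 20 noisy seeded replicates of one subject;
detector and propulsion extractors are scored against literal brute-force
oracles on 100 random traces; the Lilliefors calibration uses 2000 null
replicates of n = 24 against a 4999-sample null distribution.  The
cohort-level regression demonstration uses a reduced 150/40-stride
adaptation/post plan, which pools 96 leg-orientation points across legs,
slopes and subjects.
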