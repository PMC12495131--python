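# Methods

## The scientific question

When a heart is stopped, the arterial and venous pressures relax toward the
mean circulatory filling pressure (MCFP) — classically pictured as the single
pressure the whole circulation would assume at zero flow with the blood
instantaneously redistributed. Experimentally, however, the pressures
recorded after cardiac arrest depend strongly on *how* the arrest was induced:
a barbiturate overdose (which silences autonomic reflexes) produces a rapid,
stable arterio-venous equilibration, whereas ventricular fibrillation (VF,
which leaves the reflex arcs intact) produces a dynamic course — both
pressures rise to a peak minutes after arrest and a persistent *retrograde*
gradient (CVP above MAP) remains at ten minutes. `zeroflow` implements a
closed-loop cardiovascular model, a reflex controller, a generator of
surrogate pig recordings constrained by the experimental group statistics,
and the signal-processing/statistics chain needed to compare them — so the
whole in-silico study runs on a desk.

## The circulation model

The circulation is a closed loop of 21 two-element Windkessel compartments
in the tradition of Heldt's CVSim-21 human model: each compartment has an
inflow/outflow resistance `R` (mmHg·s/mL), a compliance `C` (mL/mmHg) or —
for the four cardiac chambers — a time-varying elastance `E(t)` bounded by
`E_min` (diastole) and `E_max` (mid-systole), and an unstressed volume `V0`.
Pressure follows the linear law `P = (V − V0)/C + P_ext`; flow is Ohmic,
`Q = ΔP/R`, rectified on the four cardiac valves (ideal diodes). Thoracic
compartments feel a common intrathoracic pressure: a breath-synchronous
waveform at baseline, zero after arrest (ventilator disconnected).
Ventricular activation is a raised half-sine whose systolic duration scales
with the square root of the cycle length; atria lead the ventricles.

The compartment volumes are the state variables
(`dV_i/dt = ΣQ_in − ΣQ_out`). Because the published CVSim parameter table is
not reproduced in the packaged configuration verbatim, `human_default.yaml`
is a reconstruction from the literature of this model family, adjusted so
that the closed loop settles at a textbook healthy-adult operating point
(MAP ≈ 95 mmHg, CO ≈ 5 L/min, CVP ≈ 2–5 mmHg, whole-circulation zero-flow
equilibrium ≈ 9 mmHg). All parameters live in the YAML configuration and are
overridable.

### Numerics

The network node time constants range from ~1 ms (aortic arch) to minutes
(venous redistribution), so the system is stiff. Each step is integrated
with a fixed-step **backward Euler** scheme: valve (and rectified-arteriole)
states are frozen from the pressures at the start of the step, making the
step linear in `V`, and one 21×21 solve advances the state. This is
unconditionally stable, conserves total blood volume to solver round-off
(the flow matrix has zero column sums), and relaxes to the *exact*
equilibrium of the linear network — which the MCFP oracle tests require.
The step is 1 ms during the beating baseline and 5 ms after arrest, when
the dynamics are slow; a dt-halving test checks first-order convergence,
and a 3-compartment reduction is verified against an independent
dense-output LSODA solution. Sub-mL transient volume undershoots of the
smallest chambers at beat transitions are tolerated; volumes below −1 mL
abort the run with a state dump.

### Zero-flow equilibrium (the analytic MCFP)

With activation off, every chamber relaxes to its diastolic elastance
(floored at a configurable `epsilon_elastance`, default 1e-3 mmHg/mL), so
the arrested network is linear with effective compliances
`C_eff = C` (passive) or `1/max(E_min, ε)` (cardiac), and the common
equilibrium pressure is

```
P_eq = (V_total − Σ V0) / Σ C_eff
```

This closed form is the oracle against which reflex-off simulations are
tested (plateau within 0.1 mmHg, across random parameter perturbations and
both volume states). We deliberately do *not* implement "elastance to zero"
literally: a chamber with `E = 0` is an infinite-compliance reservoir pinned
at its external pressure, which would swallow the entire stressed volume and
drive every pressure to ~0 — irreconcilable with the ~15 mmHg zero-flow
plateaus the model must reproduce. Arrest therefore means *activation* to
zero: the heart becomes a set of passive diastolic reservoirs.

### One-way elements beyond the cardiac valves

Two rectifying mechanisms, both config-switchable, are required for the
reflex-on phenomenology and are motivated by the physiology of the arrested
circulation:

* **Arteriolar rectification** (`rectify_microcirculation`): the four
  systemic microcirculatory resistors pass forward flow only
  (Starling-resistor-like arteriolar collapse under a retrograde gradient).
  A purely linear R-C loop cannot hold CVP above MAP for minutes — any
  retrograde path re-equalises the two sides within seconds — so a
  rectifying element is structurally necessary for a persistent retrograde
  gradient.
* **Trans-cardiac obstruction after arrest** (`arrest_valve_r_factor`,
  `arrest_tone_valve_gain`): an arrested heart is no longer a low-resistance
  conduit. The valved-edge resistances rise by a base factor (default 200)
  after arrest and, in proportion to the sympathetic contractility drive, by
  a much larger tone-dependent factor — the sympathetically driven ischemic
  myocardium maintains wall tension and functionally obstructs trans-cardiac
  flow, whereas the flaccid reflex-silent heart remains a weak passive
  conduit. This is what lets a reflex-off arrest equilibrate fully to the
  analytic MCFP while a reflex-on arrest holds its arterio-venous gradient
  through the ten-minute window. `ignore_valves` switches every diode off
  (used by the equilibrium oracle in its valve-free form).

Pressure-volume laws stay linear throughout; there is no collapse law for
compartments whose pressure falls below the external pressure. This is a
known limitation of the model family.

## The reflex controller

Short-term pressure regulation is a discrete-time arterial baroreflex (ABR)
plus cardiopulmonary reflex (CPR), ticked at the 200 Hz sampling rate, in
four stages:

1. **Afferent smoothing** — aortic-arch pressure, its pulse pressure
   (max − min over a 2 s window) and right-atrial pressure are averaged over
   250 samples (1.25 s).
2. **Error + saturation** — the smoothed signals are offset against set
   points and passed through the odd arctan characteristic
   `φ(e) = (2L/π)·arctan(πe/(2L))` with unit slope at zero and asymptotes at
   the scaling limits (18 for ABR, 5 for CPR).
3. **Convolution** — the saturated errors drive unit-area triangular
   impulse-response kernels, one per arc: a fast parasympathetic arc
   (support ~1 s) and slow sympathetic arcs. The triangular convolution is
   evaluated recursively (the kernel's second difference is two moving-window
   sums), so the cost per tick is O(1) regardless of kernel span.
4. **Static gains** — the efferents map onto heart rate (additive, bpm),
   ventricular contractility and arteriolar resistance (fractional scales,
   floored at 0.1), and unstressed volume (additive, mL, distributed over
   the venous reservoirs with a small arterial share; clamped so no
   compartment loses more than 75 % of its resting `V0`).

Sign conventions are ordinary negative feedback: pressure above set point
slows the heart, dilates, and raises unstressed volume. With all gains zero
the controller is a bit-exact no-op (property-tested), and corrections fade
in over 5 s when the controller engages so that warm-starting cannot step
the state.

The slow-arc kernel spans are in the order of 10²–10³ s. The fast/slow
split and the unit-area triangular shape are standard; the *constants* are
not published anywhere for this configuration, and the post-arrest peak at
~300 s fixes their scale: the venous CPR arc must lag the sympathetic
venoconstriction by minutes for the pressures to rise, overshoot and
partially relax. A fourth arc (`cpr_art` in the pig configuration) carries
the late arterial-tone component: under prolonged ischemia arteriolar tone
fails later than venous tone, which is what pulls the isolated arterial tree
below the venous plateau at late times (the retrograde gradient).

## Scenarios

Four in-silico arms mirror the experimental design: euvolemia or 20 %
hypovolemia (proportional volume withdrawal before baseline stabilisation)
× reflexes on or off. Arrest is instantaneous at t = 0: heart rate,
respiratory rate and cardiac activation are set to zero; the controller
keeps running when reflexes are on (pulse pressure collapses to zero, which
saturates the arterial error). Pentobarbital arrest is represented *only* as
reflex inactivation — no pharmacokinetics. Each run performs an open-loop
lead-in (default 15 s), engages the controller, requires the baseline to be
periodically steady (mean aortic drift below a tolerance per 5 s; a failed
check raises with advice), then integrates 600 s past arrest, recording ABP
at the abdominal aorta, CVP at the right atrium and CO as pulmonary-artery
flow at 200 Hz.

## Synthetic pig recordings

The experimental data exist in the package only as group mean ± SD at four
analysis points (T0 = −20 s, T1 = 30 s, T2 = 300 s, T3 = 600 s) for three
groups. The generator turns those anchors into per-animal 200 Hz recordings:

* the group mean curve is flat at the T0 value before arrest, relaxes
  exponentially (τ = 4 s, blended so the 30 s anchor is met exactly) and
  follows a shape-preserving monotone piecewise cubic (PCHIP) through the
  30/300/600 s anchors; CO drops to exactly zero at the arrest instant;
* a synthetic pulsatile carrier (pulse pressure ≈ 30 mmHg at HR 100 min⁻¹)
  rides on the pre-arrest segment purely so the 0.5 Hz filter has realistic
  work to do;
* between-animal dispersion is a per-animal z-score (correlated across
  channels, ρ = 0.8 — animals are congested or dry as a whole) scaled by the
  PCHIP-interpolated SD trajectory, so group SDs match the printed values at
  every time point, not just baseline; within-trace noise is band-limited
  Gaussian (2 mmHg);
* everything is deterministic per seed with independent per-animal
  substreams.

With noise and offsets at zero the pipeline (filter + time-point extraction)
reproduces every anchor mean to better than 0.1 mmHg — the round-trip
property that validates the processing chain. What passing these tests does
**not** show: the generator has no beat morphology, no respiratory
modulation of the pressures, no inter-animal heart-rate variation — it is a
group-statistics-faithful surrogate, not a waveform model of a pig.

## Processing and comparison chain

* **Mean signals**: third-order Butterworth low-pass at 0.5 Hz applied
  forward and backward (zero phase; squared magnitude response
  `1/(1+(f/0.5)⁶)`, verified at 2 Hz against the closed form), edges handled
  by reflection.
* **Time points**: values at −20/30/300/600 s as ±1 s window averages
  (robust to residual ripple; a window clipped by the record end uses its
  available part).
* **Normalized RMSE**: RMSE between simulated and reference mean curves
  over 0–600 s post arrest, divided by the reference range over that window,
  in percent; below 5 % is read as high agreement. Range normalization (not
  mean) was chosen because the comparison curves have large dynamic range
  and near-zero segments; both window and denominator are arguments.
* **Statistics** (delegated to pingouin/scipy at contract level): one-way
  repeated-measures ANOVA for within-group change over 30–600 s, a mixed
  ANOVA (group between, time within) for the group×time interaction against
  the pentobarbital arm, paired t-tests for CVP vs MAP at 600 s, and
  Shapiro-Wilk screens. All p-values two-sided, α = 0.05, no multiplicity
  correction beyond the per-contrast level. A Monte-Carlo test confirms the
  interaction test holds its nominal type-I rate on null cohorts.

## Pig calibration

`pig_calibrated.yaml` is derived from the human configuration by
`scripts/calibrate_pig.py`, in three documented stages: (1) geometry scaled
to a ~40 kg animal and total blood volume set so the *analytic MCFP equals
the pentobarbital-group zero-flow plateau* (the reflex-free zero-flow
pressure is the model's MCFP — that identification is the calibration's
backbone); (2) microcirculatory resistance, venous-return resistance,
ventricular elastance and arterial stiffness iterated until the reflex-on
baseline reproduces the VF-euvolemia baseline anchors (MAP 53, CVP 11,
CO 3 L/min, arch pulse pressure ≈ 30 mmHg, under positive-pressure
ventilation), with reflex set points then pinned at the achieved operating
point (an anesthetised pig defends its own baseline, not 95 mmHg);
(3) seven reflex shape scalars (two unstressed-volume gains, two kernel
time scales, the arterial-tone gain and share, a resistance-gain scale)
tuned by Nelder-Mead against the noiseless VF-euvolemia reference curve,
minimizing the mean range-normalized RMSE of MAP and CVP. The tuning vector
and score are stored in the YAML for reproducibility.

## Problem sizes and defaults

Simulations integrate ~60 s of baseline plus 601 s of arrest at 1 ms/5 ms
steps and record at 200 Hz; synthetic cohorts default to 14 animals
(7 pentobarbital, 4 VF-euvolemic, 3 VF-hypovolemic) at 200 Hz, and the
statistics calibration runs its Monte-Carlo at 25 Hz (well above twice the
0.5 Hz analysis cutoff), sizes chosen so the whole desk-scale study runs in
minutes on one core.

## Known limitations

* Linear pressure-volume laws everywhere: no vessel collapse, no
  volume-dependent compliance, no ischemia-induced wall-property changes.
* The trans-cardiac obstruction and arteriolar rectification are effective
  (lumped) descriptions of Starling-resistor physiology, not mechanistic
  valve models; their factors are config knobs, not measurements.
* Reflex kernel constants are calibrated, not measured; different
  kernel/gain combinations can produce similar trajectories
  (identifiability is limited by three anchor points per channel).
* The synthetic recordings inherit everything the four anchors cannot
  constrain: the true inter-anchor course of the experimental curves is
  interpolated, not known.
* No resuscitation, no vasoactive drugs, no gas exchange, no pericardium.
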