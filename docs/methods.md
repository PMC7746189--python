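# Methods

## Model structure and assumptions

The virtual patient is a deterministic 13-state ODE system driven by three
exogenous inputs: subcutaneous insulin infusion `ui` (U/min), subcutaneous
glucagon infusion `ug` (unit/min, with 1 mg ≡ 1 unit), and meal
carbohydrate. The subsystems and their state variables are listed in
`glucosim.model`'s docstring. Key modelling assumptions:

- Subcutaneous insulin splits between a slow and a fast absorption channel
  at a fixed per-patient fraction `pi`; each channel is a linear
  two-compartment chain, so insulin PK is linear time-invariant up to the
  diurnal multiplier `Im(t)`.
- `Im(t)` multiplies absorbed insulin only, not the background appearance
  `ci`: the background term models residual/hepatic appearance that is not
  routed through the subcutaneous depot.
- Insulin action is three independent first-order lags of plasma insulin
  concentration; the 10–30-min delay between plasma insulin and its effect
  is captured entirely by the filter time constants `ka1..ka3`.
- Endogenous glucose production is proportional to plasma glucagon and
  linearly suppressed by the remote insulin effect `x3`. The suppression
  factor `(1 − x3·Se·1e-4)` is clamped at zero, which is the only reading
  of the on/off branch that is dimensionally consistent and guarantees
  EGP ≥ 0 for all states.
- Meal glucose appears through two gamma-shaped channels sharing the rate
  `km`; the second channel is delayed by `d` minutes, which produces the
  double-peak absorption profiles seen in mixed meals. Each gamma kernel
  integrates to exactly its share of `CHO·5551/w` μmol/kg (5551 μmol of
  glucose per gram of carbohydrate), so carbohydrate is conserved.
- The glucose unit bridge: `Q1` is in μmol/kg and `V` in ml/kg, so
  `G = Q1/V` is μmol/ml = mmol/L with no extra constant.
- The CGM sensor is a pure first-order lag (`ks`) on plasma glucose; no
  sensor noise, drift or calibration error is modelled.

`km` is treated as a per-meal constant; intra-day variability of meal
absorption is carried entirely by the multiplicative flux `fm(t)`.

## Parameters

All rate constants are 1/min; sensitivities `St`, `Sd` (glucose transport
and disposal) and `Se` (EGP suppression) are stored in the conventional
1e-4-scaled units (1e-4 /min per mU/L and 1e-4 per mU/L) and multiplied by
1e-4 inside the equations. `Vi` is fixed at 190 ml/kg. The diurnal fluxes
`Im`, `fm` (unitless multipliers) and `Fg` (additive, μmol/kg/min) are
continuous piecewise-linear functions of clock time, periodic with period
1440 min.

The template ranges in `population.DEFAULT_TEMPLATE` are the package's own
choice of physiologically plausible adult T1D values (insulin absorption
time-to-peak ~50–100 min, insulin clearance `ke` ≈ 0.14/min, meal
absorption time-to-peak 1/km ≈ 30–55 min, glucagon time-to-peak 15–30 min,
glucose volume 140–180 ml/kg, Hovorka-range insulin sensitivities). They
are validated behaviourally, not against any published cohort: under
basal-only insulin the template patient's fasting glucose settles inside
4–12 mmol/L over 24 h (tested), and the canonical trial produces
clinically recognisable outcome magnitudes.

## Synthetic cohorts

`sample_cohort` draws each strictly positive parameter log-normally around
the template midpoint (log-sd = the spec'd coefficient of variation,
default 0.15 — a moderate inter-subject spread), and the two unit-interval
fractions `pi`, `pm` from a truncated normal. Diurnal flux multipliers are
log-normal with median 1 on an 8-knot grid per 24 h (log-sd 0.10 by
default); sampling on the log scale keeps the multiplicative fluxes
strictly positive by construction. The additive flux `Fg` defaults to zero
amplitude. Day-to-day intra-patient variability is implemented by
redrawing each patient's fluxes from their own dispersion at every
simulated day boundary.

Each patient's insulin therapy is derived self-consistently from their own
physiology: the basal rate is the infusion that balances the fasting
glucose equation at 6.5 mmol/L (solved from the steady-state insulin
chain by root-finding), the total daily dose is taken as twice the basal
share (the usual basal/bolus split), and the insulin-to-carbohydrate ratio
follows the 500 rule (ICR = 500/TDD, clipped to 2–30 g/U). Demographics
(age, BMI, HbA1c, duration) are sampled uniformly over adult T1D ranges
and only feed the baseline-characteristics table.

What the generator does **not** emulate: the joint posterior correlations
of clinically fitted patients, sensor error, exercise, circadian insulin
requirement patterns beyond the random fluxes. Passing tests therefore
demonstrate correctness of the machinery and the model's qualitative
behaviour, not quantitative agreement with any real cohort.

## Trial engine

- The dosing loop holds infusions piecewise-constant over each dosing
  interval (default 10 min) and integrates the ODE across the interval
  with an adaptive stiff-capable solver (LSODA, rtol 1e-8 / atol 1e-10).
  A controller's `step` return is interpreted as the **total** dose over
  the interval, applied as a constant rate — exact for the ODE and
  agnostic to bolus-vs-rate semantics.
- The ODE clock runs in minutes past midnight so diurnal fluxes line up
  with wall-clock knots; trial-relative times are converted at the engine
  boundary.
- Meals are announced to the controller at the dosing step containing the
  mealtime; the model always receives the true carbohydrate amount, the
  controller the announced amount. Carb-counting error is uniform on
  ±20%, independent per meal, rounded to 1 g and kept inside the 0–20%
  envelope after rounding.
- Rescue carbohydrates: when sensor glucose drops below 3.3 mmol/L
  (configurable), 16 g of unannounced carbohydrate is given with a 15-min
  lockout between rescues. All three values are protocol fields.
- Initial state: `Q1 = G0·V` with `G0` = protocol starting glucose plus
  optional Gaussian noise (redrawn if non-positive); the insulin chain is
  preloaded at the steady state of a basal rate consistent with the
  configured insulin-on-board (IOB divided by the depot's mean residence
  time), or the patient's programmed basal when no IOB is given; `Q2`
  starts at its conditional steady state; glucagon compartments start
  empty.
- Determinism and order independence: every random draw comes from a
  `numpy` generator seeded with `[protocol.seed, patient_index, stream]`,
  so per-patient runs are pure functions of (cohort, protocol, seed) and
  independent of execution order.
- Fault isolation: controller exceptions, NaN/negative doses are caught
  per patient; the run is marked `controller-failed at t=...` and its
  trace frozen, while all other patients complete. Glucagon returned in a
  non-dual arm is suppressed to zero with a logged warning rather than
  failing the run.
- Loop-loss windows (optional protocol field) skip the controller and fall
  back to the programmed basal, emulating a lost sensor/algorithm
  connection.

## Reference controllers

- **Open-loop**: constant programmed basal plus meal boluses of
  announced CHO / ICR. The comparator arm.
- **Single-hormone**: open-loop plus a glucose-responsive basal — full
  suspend below 4.5 mmol/L, linear taper to normal by 6 mmol/L, and a
  modest scale-up (15%/mmol/L, capped at 2×) above 10 mmol/L.
- **Dual-hormone**: the single-hormone logic plus glucagon-on-low: a
  0.15 mg mini-bolus when sensor glucose drops below 4.3 mmol/L, with a
  30-min lockout. Building the dual arm on top of the suspend rule
  mirrors how clinical dual-hormone systems behave and makes the expected
  hypoglycemia ordering (dual ≤ single ≤ open-loop) a structural
  property rather than a tuning accident.

These are deliberately minimal: they exist as comparators and engine
exercisers, not as competitive control algorithms.

## Outcome metrics

Percent-time metrics attribute one sampling interval to each sample;
AUC uses trapezoidal integration with exact linear interpolation at
threshold crossings, reported in mmol/L·min; event incidence uses a
hysteresis rule — after an excursion past a threshold, a new event is
counted only after recovery beyond threshold + 0.6 mmol/L (below
threshold − 0.6 for hyperglycemia) — so a single wobbling excursion
counts once. Both 3.3 and 3.1 mmol/L hypoglycemia thresholds are computed
(the field uses both); incidence defaults to 3.3. The nocturnal
sub-report restricts samples to the 23:00–07:00 clock window
(configurable). Insulin delivery is reported both as U/h (trace mean) and
U/kg/day. Failed runs are excluded from outcome tables and listed in the
report's status map.

## Numerical choices

- LSODA per dosing interval; meals enter as a smooth forcing inside the
  interval, infusions as constants, so no discontinuities cross a solver
  window except at interval boundaries.
- The raw right-hand side evaluates at `max(y, 0)`: adaptive solvers probe
  slightly negative trial states near 0, and clamping at evaluation keeps
  outflows zero at the origin without changing the physical dynamics.
  If an accepted endpoint is still negative beyond 1e-9 relative, the
  interval is re-integrated at 100× tighter tolerance, then clamped with
  a logged warning.
- Meals older than `20/km + d` minutes are dropped from the active
  forcing set (kernel tail < 1e-8 of its mass).
- Tightening the tolerance from rtol 1e-8 to 1e-10 changes end-of-window
  glucose by < 1e-6 mmol/L on the standard six-hour meal-plus-bolus
  fixture (tested).

## Problem sizes

The test and acceptance battery uses: 100 random parameter draws for the
linear-subsystem oracle (24 h each), 100 draws for carbohydrate
conservation, 20 for glucagon peak timing, 10⁴ meals for the
carb-error envelope, 2000 patients for the sampling-dispersion check, and
the canonical 15-patient, 24-hour, 10-min-step trial (three arms) for all
engine-level and outcome-level checks. These sizes give Monte-Carlo
errors well below the asserted tolerances while keeping the whole suite
under a minute of compute.

## Known limitations

- Cohorts are synthetic; no claim of quantitative agreement with any
  clinical population. Parameter draws are independent across parameters
  (no posterior correlation structure).
- No sensor noise/drift, no exercise physiology, no pump occlusion or
  connectivity faults beyond the explicit loop-loss window.
- The EGP branch and the additive diurnal glucose flux follow the clamp /
  μmol-kg-min readings argued above; alternative readings of the source
  model exist but are dimensionally inconsistent.
- Glucagon "units" are identified 1:1 with mg at the dosing interface;
  reported glucagon delivery is in mg.
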