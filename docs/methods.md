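# Methods

## Model

The circulation is a closed hydraulic loop in the electrical analogy:
pressures (mmHg) are voltages, flows (mL/s) currents, compliances (mL/mmHg)
capacitors, inertances (mmHg·s²/mL) inductors.  Units are mmHg / mL / cm / s
everywhere; no conversions occur inside the package.

### Chambers

Each chamber is a truncated ellipsoid with constant long-axis length `l`
and scaling coefficient `K`:

    V = (4/3) π K r² (l / a),     a = 2 (LV, LA, RA),  a = 4 (RV).

`K` absorbs long-axis shortening and geometric irregularity; it links the
diameter signal to the volume signal without affecting pressures — scaling
`K` by c at fixed volume scales the radius by c^(−1/2) and leaves the
pressure–volume dynamics untouched (verified as a property test on the full
loop).  The RV divisor a = 4 models its crescentic cavity as an ellipsoid
trimmed at both the long and the basal axis; consistently, the reported RV
"basal diameter" equals the RV radius rather than twice it.

Ventricular pressure is active + passive:

    p = E_es (V − V₀) f(t)  +  A e^{BV} − 1,

with the raised-cosine activation

    f(t) = (1 − cos(π t/T₁))/2            0 ≤ t < T₁
           (1 + cos(π (t−T₁)/(T₂−T₁)))/2  T₁ ≤ t < T₂
           0                              T₂ ≤ t < T,

so f peaks at exactly 1 at end-systole T₁ and E_es is the true
end-systolic elastance.  Time is reduced modulo T; every piecewise boundary
is half-open.  The passive law is implemented with the operator order
`A·exp(BV) − 1`; the alternative reading `A·(exp(BV) − 1)` differs only by
the constant A − 1 (relevant only when A ≠ 1, i.e. in DCM) and is available
behind the `subtract_A` switch.  The default reading reproduces the
reference hemodynamics in all four scenarios, so it is kept.

Atria use a time-varying elastance

    p = E(t) (V − V₀),   E(t) = E_min + ½ (E_max − E_min) f_a((t − D) mod T),

where f_a is zero until Ta = 0.8 T and then a single cosine bump
1 − cos(2π (t−Ta)/(T−Ta)) peaking at 2 (hence the ½).  The delay D wraps
across the cycle boundary, which places the atrial kick in late ventricular
diastole.

Chamber volumes are the ODE state; radii are recovered algebraically as
r(V).  Writing the kinematics as dr/dt instead is mathematically equivalent
by the chain rule but introduces a 1/r singularity at small volumes, so it
is avoided.

### Network

State (14 components): four chamber volumes, six compliance-node pressures
(ao, as, vs, po, ap, vp), four inertance flows (ao, as, po, ap).  Each
vessel segment has a shunt compliance at its inlet node and a series R+L to
the next node; the venous segments (vs, vp) carry no inertance and are
purely resistive–capacitive.  The four heart valves are ideal diodes —
Ohmic conduction down a positive gradient, zero reverse flow — while the
venous return paths are bidirectional resistances.  Summing chamber dV/dt
and all C·dp/dt telescopes to zero, so total stressed volume
(Σ chamber V + Σ C·p) is conserved exactly; the integrator holds the drift
below 0.1 % over 20 cycles at the default tolerances.

## Numerics

- Integrator: `scipy.integrate.solve_ivp` with BDF (stiff multistep),
  `max_step` 1 ms, relative tolerance 1e-3, absolute tolerance 1e-6 in
  model units.  The diode corners are handled by the solver's error
  control; halving `max_step` moves the mean arterial pressure by < 0.2 %.
- Periodic steady state: integration proceeds cycle by cycle; convergence
  is declared when cycle-mean LV volume and cycle-mean aortic pressure both
  change by < 1e-3 (relative) between consecutive cycles.  Typical runs
  converge in 15–25 cycles.  The returned final cycle is sampled on a
  uniform 1 ms grid spanning exactly one period; start and end states agree
  within 0.5 % componentwise.
- Initial condition: chambers at 1.5× their zero-pressure volume, the rest
  of the blood spread over the compliances at one uniform pressure, all
  inertance flows zero.  The steady state is independent of this split —
  two different distributions of the same total converge to mean arterial
  pressures within 0.5 % — so only the *total* matters.
- Calibration: the total stressed volume is the loop's one free quantity.
  A safeguarded secant iteration (bisection fallback, bracket supplied by
  the preset) drives the steady-state LV end-diastolic volume to the
  anchor — 125 mL for the healthy adult, 92 mL for the healthy child — to
  within 0.1 mL, typically in 3–5 steady-state evaluations (≈ 1460 mL and
  ≈ 672 mL respectively).  DCM scenarios are rerun at the healthy
  calibrated total: a closed circulation conserves blood, so disease
  parameters redistribute volume rather than change it.
- Determinism: there is no randomness anywhere; runs are bit-reproducible
  for a fixed platform and tolerance set.

## Clinical indices

End-diastole and end-systole are the ventricular volume extrema of the
final cycle (robust to diode chatter); atrial landmarks are the analogous
max/min volumes.  Reported quantities:

- EF = 100·(EDV − ESV)/EDV per ventricle; SV = EDV − ESV;
  CO = SV·(60/T)/1000 L/min (identical to mean aortic flow at periodic
  steady state).
- Diameters d = 2r at the landmark for LV and atria; RV basal diameter = r.
- Fractional shortening fs = 100·(EDD − ESD)/EDD.  Because d ∝ √V at fixed
  K and l, fs ≡ 100·(1 − √(ESV/EDV)).
- Sphericity index si = l / D_mid with D_mid = √3·r, the cross-section
  diameter of the model ellipsoid halfway along the long axis (the
  cross-section radius at height l/2 of an ellipsoid with apex-to-base
  extent l is r·√3/2, so the diameter is √3·r).  Dsi evaluates r at
  end-diastole, Ssi at end-systole.  This geometric convention is applied
  uniformly to all scenarios; pediatric reference values for sphericity
  computed under other conventions (e.g. with an adult long-axis length in
  the numerator) will not agree with it, and the pediatric sphericity
  indices should be compared only in direction, not magnitude.
- MAP / MPAP: trapezoidal time-average of the aortic / pulmonary-artery
  node pressure over exactly one period.

## Parameters that matter most

| Parameter | Units | Healthy adult | Effect |
|---|---|---|---|
| E_es (LV) | mmHg/mL | 2.5 | systolic contractility; ↓ in DCM (0.9) |
| A, B | mmHg, 1/mL | 1, 0.02 | passive stiffness; A ↓ in DCM (0.65) |
| V₀ (LV) | mL | 15 | zero-pressure volume; ↑ in DCM (25) |
| K (LV) | – | 1.15 | diameter↔volume scaling; 0.95 in DCM |
| R (sys. arterioles) | mmHg·s/mL | 0.95 | afterload; ↑ in DCM (1.6) |
| T | s | 0.8 | cycle length; 0.75 in the child presets |
| total stressed volume | mL | calibrated | preload; the only tuned value |

Child presets shrink lengths, V₀ and compliances, raise K and E_es, and
shorten T; vascular resistances are unchanged between the age groups.

## Scope and limitations

- Valves are ideal diodes: no regurgitation, no leaflet dynamics, no
  stenosis grading; mitral regurgitation in dilated disease is therefore
  not represented.
- No baroreflex or other compensatory feedback, and no disease
  progression — each scenario is a fixed parameter set.
- Ventricular interaction through the septum and pericardium is absent;
  the ventricles couple only through the shared loop (preload/afterload).
- The long axis is constant over the cycle; wall stress/strain and
  regional mechanics are outside a 0D model.
- The ellipsoid is a modelling surface, not an anatomical reconstruction:
  diameters and sphericity indices inherit the convention choices above
  and should be compared against echo measurements with that in mind.
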