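# Methods

## The calibration problem

Given an ionic cell model with per-current maximal conductances
G₁…G_n, `iontune` estimates new conductance values that restore
intracellular-potassium homeostasis while holding a set of
electrophysiological markers inside prescribed bands. Decision variables are
the dB-like scaled conductances x_i = 20·log₁₀(G_i/G_i⁰), which puts
conductances that differ by orders of magnitude on commensurate axes; the
default box allows each conductance a factor of ½–2 (x ∈ [−6.02, 6.02]).

The objective is the square of the one-cycle integral of the total
potassium-carrying current at 1 Hz steady-state pacing,

    I_K,tot = I_to + I_Kr + I_Ks + I_K1 − 2·I_NaK + I_CaK + I_Kp + I_stim,

with the pump entering at −2 (each pump cycle imports two K⁺ against three
Na⁺ exported, so its current understates its K flux) and the stimulus charge
assigned entirely to potassium — without that convention the budget acquires
an artefactual per-beat drift of exactly the stimulus charge. Intracellular
potassium obeys d[K⁺]ᵢ/dt = −I_K,tot·C_mem/(V_myo·F), so the objective is
zero precisely when [K⁺]ᵢ is beat-periodic.

The markers (constraints) are: APD₉₀ and triangulation = APD₉₀ − APD₅₀ at
1 Hz; systolic and diastolic [Ca²⁺]ᵢ at 1 Hz and 0.5 Hz steady state; and
τ_slow, the slow time constant of a biexponential fit to per-beat APD₉₀
after an abrupt cycle-length switch (1000 ms → 600 ms). Each marker band
[m_LL, m_UU] is folded into the canonical inequality
g = |m − m_CR|/m_RR − 1 ≤ 0 with m_CR, m_RR the band center and half-range.

## The trust-region response-surface loop

One marker evaluation costs thousands of paced beats, so the optimizer
treats the simulator as a black box:

1. **Database.** Sample a full factorial 3ⁿ design over the current
   trust-region box (center x^k, half-width Δ^k, intersected with the global
   bounds). The box is translated inward when it pokes out of the bounds so
   every axis keeps three distinct levels — otherwise the pure quadratic
   term on that axis is unidentifiable. All points go to the evaluator as
   one batch (embarrassingly parallel); the center is always included.
2. **Surfaces.** Fit full second-order polynomials (1 + 2n + n(n−1)/2
   coefficients) by ordinary least squares to the objective and to every
   marker. Regressors are centered on x^k and divided by Δ^k before the
   solve; rank deficiency raises an error naming the unidentifiable basis
   terms.
3. **Subproblem.** Minimize the objective surface subject to the marker
   surfaces staying inside their bands, the trust-region box and the global
   bounds. Marker bands enter as two smooth inequalities per marker (scaled
   by the half-range, so the geometry matches the canonical transform
   without its absolute value). SLSQP with analytic polynomial gradients is
   restarted from the box center and four deterministic corners (all-low,
   all-high, two alternating patterns) because quadratic surrogates can be
   nonconvex; the best feasible solve wins. If no start is surrogate-
   feasible the minimizer of the summed squared violations is returned,
   flagged infeasible. KKT multipliers are reconstructed by non-negative
   least squares on the active-constraint gradients over the coordinates not
   pinned at a bound.
4. **Ratio test.** The candidate is evaluated by the true simulator (a
   second, one-point batch) and compared through trust ratios
   ρ = Δtrue/Δpredicted for the objective and each marker. The step is
   accepted iff ρ₀ > 0 and either (i) the true transformed constraints are
   all ≤ 0 at the candidate, or (ii) every marker ratio lies within
   ρ_L = 0.25 of 1.
5. **Radius.** ×0.25 on rejection; unchanged on an accepted interior step;
   ×2 on an accepted boundary step, capped at Δmax.
6. **Termination.** Accepted step shorter than δ₁; or ‖∇φ‖ < δ₂ where
   φ = f̃ + Σλ_j·m̃_j is the surrogate Lagrangian over the marker surfaces
   (analytic gradient, no numerical differentiation); or Δ < δ₃; or the
   iteration budget.

Defaults: Δ⁰ = 2.0, Δmax = 6.0, δ₁ = δ₂ = δ₃ = 10⁻³, 20 iterations,
∞-norm trust region (a box — it then coincides geometrically with the
factorial sampling volume).

Two numerical guards matter in practice and are deliberate design choices:

* **Degenerate ratios.** When the surrogate predicts essentially no change,
  ρ is 1 if the true change is also negligible and ±∞ otherwise (guard
  ε = 10⁻¹²). For the *marker* ratios the relevant scale is the constraint
  band, not machine precision: a marker whose change is below 10% of its
  band half-range (`marker_guard_frac`) cannot affect feasibility, so its
  ratio is taken as 1. Without this, markers that sit at a floor (e.g.
  diastolic calcium at the resting level) produce noise/noise ratios and
  veto every step.
* **Interior margin.** The surrogate bands are shrunk by 1% of the
  half-range (`constraint_margin`), so that surrogate error of that order
  cannot strand the final iterate marginally outside the true band.

A rejected candidate shrinks the radius and the database is rebuilt around
the unchanged center; an accepted one recenters the next database. The true
objective is non-increasing along accepted iterates whenever the center is
surrogate-feasible (ρ₀ > 0 with surrogate descent).

## The toy ventricular model

The bundled model is a five-state caricature of a human ventricular
myocyte: membrane potential V; an L-type-style calcium current with
instantaneous Boltzmann activation and a slow inactivation gate f
(τ_f = 150 ms); a delayed-rectifier-style potassium current with activation
gate n (τ_n = 250 ms); an inward rectifier with the characteristic
voltage-minus-E_K dependence; a plateau potassium current; a Na/K pump; a
lumped calcium transient (τ_Ca = 60 ms) driven by the calcium current; and
dynamic [K⁺]ᵢ with E_K = (RT/F)·ln([K⁺]ₒ/[K⁺]ᵢ). It produces ~180 ms action
potentials with a calcium transient and rate dependence, and is stiff enough
to exercise the pipeline while integrating in well under a millisecond per
beat.

Three of its parameters were fixed once by calibration of the model's own
dynamics, and are part of the model definition:

* **Stimulus** −40 pA/pF for 2 ms: comfortably above the ~−25 mV activation
  threshold of the calcium current (a weaker pulse fails to elicit an AP).
* **Pump regulation.** The Na/K pump is multiplied by a sigmoid in [K⁺]ᵢ
  (midpoint 138 mM, slope 20 mM). This is the physiological stabilizer of
  intracellular potassium in lumped form; it gives the model a genuine slow
  relaxation of [K⁺]ᵢ and hence an identifiable τ_slow (~94 s at the
  defaults, the scale reported for human ventricular models). Without it
  the potassium pool relaxes over hours and the slow adaptation amplitude is
  unidentifiable within any practical protocol.
* **G_NaK = 0.98424** and the initial state at the model's computed resting
  point (V ≈ −87.30 mV, [K⁺]ᵢ = 138 mM): chosen so the *unperturbed* model
  is potassium-balanced at 1 Hz — its one-cycle ∫I_K,tot is ~10⁻³ ms·pA/pF
  after 300 beats. The calibration scenario then has a clean premise:
  perturbing conductances (default G_K1 ×1.3, G_Ca ×0.85) breaks the
  balance (|∫| ≈ 7 ms·pA/pF) and the optimizer must restore it.

κ_K = C_mem/(V_myo·F) = 5·10⁻⁴ mM/((pA/pF)·ms) sets the [K⁺]ᵢ relaxation
time; k_conv = 1.5·10⁻⁶ converts the calcium current into the transient.

## Protocols and markers

* Steady-state pacing delivers a stimulus train at fixed CL from the
  model's initial state; "steady state" is by fixed beat count
  (3000 in the `paper` profile, 300 in the `test` profile), not a
  convergence criterion.
* Per-beat records use a 0.1 ms output grid; the final beat is re-integrated
  on a 0.02 ms grid (with a 1 ms step cap so that dense-output interpolation
  stays below the trapezoid tolerance) and carries the current time series.
* The per-beat ∫I_K,tot is read off the integrator's own [K⁺]ᵢ increment
  (−ΔKᵢ/κ — exactly the same quantity, at integrator accuracy); the final
  trace's integral is computed by trapezoid on the current series, and the
  two routes agree to <10⁻⁶ mM equivalent.
* AP onset is defined at stimulus delivery (robust for slow upstrokes;
  max-dV/dt onset available as an option); V_rest is read 1 ms before the
  stimulus, the peak over the whole cycle; APD crossings are linearly
  interpolated. An AP counts as captured only if V exceeds −20 mV within
  50 ms of the stimulus.
* The adaptation fit y(t) = y_inf + A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s) is
  solved by Levenberg–Marquardt from a 3×3 deterministic grid of time-
  constant starts (τ_f ∈ {2,10,30} s, τ_s ∈ {60,90,120} s), time constants
  in log space, uniform weights; components are relabelled so τ_fast <
  τ_slow, ties broken toward an identifiable slow amplitude; |A_s| < 1 ms
  flags τ_slow unidentifiable.

## Integration

Two routes share one interface. Generic contract models (e.g. CellML
imports) integrate with scipy's BDF at rtol 10⁻⁶ and per-state absolute
tolerances (10⁻⁶ for mV-scale states and gates, 10⁻⁹ for mM-scale
concentrations). The toy model has a compiled fast path: an adaptive
Dormand–Prince RK45 (same tolerances, 5 ms step cap) with cubic-Hermite
dense output, JIT-compiled with numba. The toy model is only mildly stiff —
its fastest quiescent time constant is ~10 ms and the upstroke is
accuracy-limited, not stability-limited — so the explicit pair is accurate
and roughly two orders of magnitude faster than a Python-callback implicit
solver. The two routes are cross-checked against each other in the test
suite (≤0.05 mV on a stimulated beat).

## Sensitivity analysis

One-at-a-time ±30% perturbations (2n+1 marker evaluations) yield percent
changes D = (M_p − M_c)/M_c·100 and centered sensitivities
S = (D₊ − D₋)/(2a) with a in percent, so unit elasticity gives S = 100%.
An alternative literal scaling carrying an extra factor of 100 exists in
the field's formulas; it is available as `convention="literal"` and differs
only by that constant, which cancels in rankings and normalized heatmaps.
Decision-variable selection ranks by |S| on the objective and excludes any
conductance that uniquely dominates a marker (|S| above a dominance
threshold, default 50%) that no other candidate can compensate (all others
below 20%) — calibrating with such a conductance would distort that marker
irrecoverably. On the toy model this excludes the pump conductance, which
uniquely controls τ_slow.

## What the synthetic fixtures do and do not show

The analytic problem (quartic objective, two quadratic markers with bands)
has a brute-force grid oracle; agreement there validates the optimizer
machinery — sampling, fitting, subproblem, acceptance — independent of any
ODE. The toy scenario validates the full pipeline: marker extraction,
evaluator batching, and homeostasis restoration under marker constraints at
desk scale (300-beat steady states, 2-minute adaptation segments). Passing
it shows the method is implemented correctly, not that any particular human
ventricular model is well calibrated: real models have far more states,
currents with overlapping roles, slower potassium pools (hence longer
protocols), and markers whose experimental bands are uncertain. The `paper`
protocol profile (3000 beats, 8-minute segments) exists for full-scale runs
but is not exercised by the test suite.

## Known limitations

* The acceptance rule can accept a candidate through the ratio criterion
  while a true constraint is (slightly) violated; the interior margin makes
  this cosmetic at the defaults, but a pathological marker surface could
  still terminate marginally infeasible.
* τ_slow from a 2-minute post-switch window is biased low when the true
  constant approaches the window length; within one calibration all points
  share the bias, but `test`-profile τ_slow values should not be compared
  against full-protocol values.
* The CellML adapter covers a single-component, content-MathML subset
  (algebraic assignments + first-order ODEs); imports/units/multiple
  components are out of scope.
* Full factorial databases scale as 3ⁿ; beyond ~6 decision variables a
  different sampling design would be needed.
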