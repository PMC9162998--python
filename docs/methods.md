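# Methods

## Circulatory equilibrium

The hemodynamic state is the intersection of three surfaces in
(CO, P_LA, P_RA) space: logarithmic Frank-Starling curves for each
ventricle, CO = S·(ln(P − P0) + k), and a planar venous-return surface,
CO = (V − G_L·P_LA − G_R·P_RA)/W. Mean arterial pressure closes the system
through AP = R·CO + P_RA; R is defined as the pressure drop across the
systemic circulation, (AP − P_RA)/CO, which is dimensionally exact (the
difference from AP/CO is small because P_RA ≪ AP).

The curve/surface shape constants are population values of the canine
circulatory-equilibrium framework and are configuration, not code:

| constant | default | units | meaning |
|---|---|---|---|
| P0_L, P0_R | 2.03, 2.13 | mmHg | preload offsets of the Starling curves |
| k_L, k_R | 0.80, 1.90 | — | additive constants of the log-preload term |
| W | 0.129 | min | venous-return CO coefficient |
| G_L, G_R | 0.424, 1.31 | ml·kg⁻¹·mmHg⁻¹ | venous-return pressure coefficients |

All flows and volumes are normalized per kg body weight (CO in
ml·min⁻¹·kg⁻¹, V in ml·kg⁻¹); `body_weight_kg` in the run config is used
only to report absolute cumulative doses.

**Forward solver.** Both Starling curves invert in closed form
(P = P0 + exp(CO/S − k)), reducing the 3-equation system to a single
residual in CO, f(CO) = W·CO + G_L·P_LA(CO) + G_R·P_RA(CO) − V, which is
strictly increasing, so a bracketed root is unique. It is bracketed on
(0, co_max] (co_max 1000 ml·min⁻¹·kg⁻¹ by default) and solved with Brent's
method at xtol 1e-10. The exponent of the curve inversion is capped at 700
so bracketing stays finite; the capped branch only ever signals
infeasibility. Infeasible parameter sets (V too low to sustain positive
venous return, or no root below co_max) raise a diagnostic error rather
than returning garbage.

**Inverse map.** One measured state gives the four parameters in closed
form (S_L, S_R from the curves, R from the pressure drop, V from the
venous-return plane). Forward and inverse are exact inverses; the test
suite checks the round trip to 1e-6 relative on 1000 random states and the
solver against a plain bisection oracle.

**Target determination.** Given AP\* and P_LA\* (clamped to ≥ 70 mmHg and
≤ 18 mmHg — the safety rules of the control protocol), S_R and R are held
at their estimates and the pair CO\* = (AP\* − P_RA\*)/R,
P_RA\* = P0_R + exp(CO\*/S_R − k_R) is solved by the same bracketed root
finder; S_L\* and V\* follow in closed form. Clamping is recorded in the
returned targets. Plugging (S_L\*, V\*) back into the forward solver
reproduces (AP\*, P_LA\*) to the solver tolerance, which is tested.

## Controllers

Control runs at one decision per 10 s on measurements smoothed by a 90-s
moving average (9 control samples). The smoothing window is a free design
choice: the experimental systems this emulates average a 200-Hz signal, and
90 s keeps single-sample noise from triggering the discontinuous furosemide
branch while adding only ~45 s of lag, negligible against the ~6-min
pharmacokinetic time constant.

* **PI landiolol controller**: u = Kp·ΔS_L + Ki·∫ΔS_L dt, clamped to
  [0, u_max]. Anti-windup is conditional integration: the integral is not
  advanced on steps where the unclamped output saturates and the error
  would push further into saturation — the simplest scheme with a testable
  contract (output leaves saturation within one step of error reversal).
  Defaults Kp = 8, Ki = 1 (µg·min⁻¹·kg⁻¹ per slope-unit), u_max = 100
  µg·min⁻¹·kg⁻¹, tuned once so the default patient settles within 15 min
  with no AP undershoot; with them the loop converges to ≈ 25
  µg·min⁻¹·kg⁻¹ at steady state.
* **Nonlinear volume controller**: dead band 1.0 ml/kg on ΔV = V − V\*;
  deficits beyond the band command dextran at 1.0 (ml·min⁻¹·kg⁻¹ per
  ml·kg⁻¹ of deficit), capped at 1.0 ml·min⁻¹·kg⁻¹; excesses command a
  fixed 5-mg furosemide bolus with a 10-min lockout. The dead band plus
  fixed-bolus-plus-lockout law is this package's concrete instantiation of
  a "nonlinear controller" block; published descriptions of such systems
  specify only the block, not its internals. A consequence of bolus
  quantization is a small steady-state volume offset (≲ 0.7 ml/kg with the
  defaults), visible as a ≈ 1 mmHg bias below target in AP and ≈ 0.5 mmHg
  in P_LA.

Targets are computed once at loop activation from baseline measurements
averaged over 3 min (emulating the pre-activation stabilisation period);
`target_policy="every_step"` recomputes S_L\*/V\* from the current S_R, R
estimates instead.

## Virtual patient

The plant is the same equilibrium model with drug-dependent S_L and V:

* **PK**: one-compartment landiolol kinetics, dC/dt = rate/Vd − k_e·C,
  advanced by its exact constant-rate solution each step. Defaults: 4-min
  half-life (ultra-short-acting), Vd = 300 ml/kg. k_e = 0 is accepted as
  the no-elimination limit for mass-balance checks.
* **PD**: S_L = S_L,base·(1 − Emax_SL·C/(C + EC50_SL)), and analogously HR.
  Defaults Emax_SL = 0.4, EC50_SL = 1.45 µg/ml, Emax_HR = 0.6,
  EC50_HR = 1.1 µg/ml. These are calibration choices, not measured canine
  values: they are set so that holding the default targets requires
  ≈ 26 µg·min⁻¹·kg⁻¹ of landiolol and drops HR from 129 to ≈ 105 bpm —
  the operating range reported for such systems. HR is informational only;
  it feeds nothing in the equilibrium.
* **Volume**: dextran adds `dextran_fraction` (default 0.8, colloid
  retention) of the infused volume to V; a furosemide bolus queues
  gain·dose (default 0.5 ml·kg⁻¹ per mg) of diuresis expressed first-order
  at 0.15 min⁻¹ (τ ≈ 7 min, a realistic onset for intravenous furosemide).
* **Noise**: independent zero-mean Gaussian per signal per 10-s sample
  (SD: AP 1, P_LA 0.5, P_RA 0.5 mmHg; CO 3 ml·min⁻¹·kg⁻¹; HR 2 bpm), all
  driven by one seeded generator; runs are bit-reproducible given the seed.
* **Baseline**: the default patient is built by inverting the
  heart-failure state AP 87 mmHg, P_LA 17 mmHg, P_RA 9.1 mmHg, CO 118
  ml·min⁻¹·kg⁻¹, HR 129 bpm, so the drug-free plant is exactly at that
  equilibrium. `ensemble_cv` > 0 with a seed perturbs the baselines
  log-normally for ensemble studies.

S_R and R are constant under landiolol by default (β-blockade modeled as
left-sided inotropy/chronotropy only). One visible consequence: lowering
S_L and AP at constant R needs only a ~10% CO reduction in the plant,
whereas real failing dogs show larger CO drops with rising R, and they
receive net dextran where the self-consistent plant generates a small
volume *excess* (handled by furosemide). Passing tests therefore
demonstrate the estimator/controller logic, not the fidelity of canine
drug response; right-side or resistance effects can be added through the
patient config by replacing the constant-R assumption.

## What the simulations show (and don't)

With all defaults (noise on), the closed loop settles within 15 min,
holds max |PE| for AP and P_LA below ~8% over 15–60 min across seeds,
keeps AP within its acceptable range 100% of the time and never lets mean
AP approach the 70 mmHg floor (minimum ≈ 75 mmHg). These are properties of
the controller against *this* plant: the generator does not emulate
reflex compensation, drug response variability between subjects (beyond
optional baseline dispersion), ventilation/anesthesia effects, or any
beat-by-beat pulsatility — the model controls means only.

Problem sizes used by the test suite and acceptance script: 60-min runs at
10-s steps (361 control samples), a 20-seed noise ensemble for the P_LA
time-in-range median, and 100–1000 random draws for the solver and
round-trip property checks.

## Numerical and degenerate-input choices

* Even-length medians are the mean of the two central values.
* The PE window [15, 60] min includes t = 15 exactly; sample times are
  generated as i/steps-per-minute so grid points land exactly on minute
  boundaries, and window masks use a 1e-9 min tolerance.
* Time-in-range is scored over the full control period (PE statistics are
  the only window-restricted quantities); both are parameters.
* PE uses the measured (smoothed) variable in the denominator, per the
  standard definition; PE is undefined (error) where the variable is 0.
* A run of duration 0 yields the single t = 0 row and a no-metrics
  warning rather than an error.
* Rows of external tables that violate the estimation domain are flagged
  (`estimation_flag` column) with NaN parameters, never dropped.
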