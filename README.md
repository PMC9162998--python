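# hemoloop

Closed-loop β-blocker and volume therapy on the circulatory-equilibrium
model: an end-to-end simulator of an automated drug-delivery system for
acute heart failure, with the performance metrics used to score such
systems.

β-blockers protect the failing heart by lowering heart rate and myocardial
oxygen demand, but giving them during *acute* heart failure risks
circulatory collapse (hypotension, pulmonary congestion). One way out is to
place an ultra-short-acting β1-blocker (landiolol) under automatic negative
feedback of hemodynamics, together with volume therapy (dextran infusion,
furosemide boluses), so that mean arterial pressure (AP) and mean left
atrial pressure (P_LA) are held at safe target values while the drug does
its work. `hemoloop` implements that control system and a virtual
heart-failure canine patient to exercise it against, for control engineers
and cardiovascular modelers who want to study or extend such closed loops
before any animal or clinical work.

## The model

Steady hemodynamics are the intersection of two Frank-Starling curves and a
venous-return surface in (CO, P_LA, P_RA) space:

    CO = S_L (ln(P_LA − P0_L) + k_L)            left heart
    CO = S_R (ln(P_RA − P0_R) + k_R)            right heart
    CO = (V − G_L·P_LA − G_R·P_RA) / W          venous return
    AP = R·CO + P_RA                            systemic circulation

From one measured state (AP, CO, P_LA, P_RA) the four subject parameters —
Frank-Starling slopes S_L and S_R, systemic vascular resistance
R = (AP − P_RA)/CO, and stressed blood volume V — are obtained in closed
form. Given clinical targets AP\* (baseline − 10 mmHg, floor 70 mmHg) and
P_LA\* (baseline, cap 18 mmHg), the system solves for the parameter targets
S_L\* and V\*, then closes two loops every 10 s:

* **landiolol** (µg·min⁻¹·kg⁻¹): PI controller on ΔS_L = S_L − S_L\*, with
  conditional-integration anti-windup — β-blockade pulls S_L down to S_L\*;
* **dextran / furosemide**: nonlinear controller on ΔV = V − V\* — dextran
  infusion proportional to a volume deficit beyond a dead band, a fixed
  furosemide bolus (lockout-limited) on a volume excess.

The virtual patient layers one-compartment landiolol pharmacokinetics and
saturable Emax pharmacodynamics (on S_L and heart rate), dextran volume
expansion, first-order furosemide diuresis and Gaussian measurement noise
on top of the same equilibrium model.

Loops are scored with the standard closed-loop drug-delivery statistics:
performance error PE(t) = (Variable − Target)/Variable × 100, its median
(MDPE, bias), median absolute value (MDAPE, accuracy), wobble (stability),
the slope of |PE| over time (divergence, trend), plus the percentage of
time in the one-sided acceptable ranges (AP ≥ AP\* − 5 mmHg,
P_LA ≤ P_LA\* + 2 mmHg).

## Worked example

```sh
$ hemoloop simulate --seed 1 --out demo.csv
wrote demo.csv (361 rows) and demo.meta.yaml
signal    in-range %   MDAPE %    MDPE %  wobble %  divergence %/min
--------------------------------------------------------------------
AP             100.0      1.29     -1.21      0.34            0.0214
P_LA           100.0      2.22     -2.02      0.77            0.0035
PE window: (15.0, 60.0) min; in-range scored on all samples
```

The default virtual patient starts in heart failure (mean AP 87 mmHg,
P_LA 17 mmHg, CO 118 ml·min⁻¹·kg⁻¹, HR 129 bpm). The system sets
AP\* ≈ 77 mmHg and P_LA\* ≈ 17 mmHg from its own baseline measurements,
then titrates landiolol (settling near 25 µg·min⁻¹·kg⁻¹, HR falling to
≈ 105 bpm) and removes the resulting volume excess with two 5-mg furosemide
boluses. Both signals stay in their acceptable ranges 100% of the time;
the PE statistics above say the bias, accuracy and stability of control
over 15–60 min are all within a few percent. `demo.csv` holds the full
per-step log (raw/smoothed/true states, estimated parameters, drug
commands, cumulative doses); `demo.meta.yaml` records the resolved
configuration, seed, targets and cumulative doses.

The other commands: `hemoloop metrics demo.csv` re-scores a table (targets
read from the sidecar or given with `--ap-target/--pla-target`),
`hemoloop estimate demo.csv` appends per-row parameter estimates, and
`hemoloop fixtures` writes the small deterministic files used by the test
suite. Everything is also available as a library:

```python
import hemoloop as hl
patient = hl.make_hf_patient()
result = hl.run_closed_loop(patient, hl.ProtocolConfig(), seed=1)
print(result.targets.AP_star, result.table.AP.min())
```

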