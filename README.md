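# pbpksim

Flow-limited physiologically-based pharmacokinetic (PBPK) model simulation,
with SBML Level 3 exchange and machine-checkable reproducibility reporting.

## Who this is for

Pharmacokinetic and toxicokinetic modelers who need a small, fully
transparent compartmental simulator: a central blood pool connected to N
perfused tissues, intravenous-infusion dosing as discrete events, and every
number auditable — weight/flow closure checks, a conservation audit on each
run, and a closed-form steady state to verify trajectories against.

## The model

The state is the amount of chemical A_i (mg) in blood and in each tissue.
Distribution is *flow-limited*: venous blood leaving tissue *i* is at
equilibrium concentration C_i / PC_i, where PC_i (L/kg) is the
tissue:blood partition coefficient. An eliminating organ (extraction ratio
ER_i) removes a fraction of the chemical per pass. With Q_i the tissue
blood flow (L/min), C_blood = A_blood / V_blood, C_i = A_i / W_i:

    dA_blood/dt = Σ_i Q_i (C_i / PC_i − C_blood) + Dosing(t)
    dA_i/dt     = Q_i (C_blood − C_i / PC_i) − Q_i ER_i C_blood

Dosing(t) is a constant infusion rate inside the exposure window and 0
outside. Clearance is CL = Σ_i Q_i ER_i C_blood (mg/min). Physiological
consistency requires W_blood + Σ W_i = BW and Σ Q_i = QC (cardiac output).
Under constant infusion the bounded steady state is

    C_blood_ss = Dose / Σ_i Q_i ER_i,   C_i_ss = PC_i (1 − ER_i) C_blood_ss.

The package ships reference adult-man and adult-woman physiology (body
weight 73 / 60 kg, blood volume 5.3 / 3.9 L, cardiac output 6.5 / 5.9
L/min, liver at 2.6 % of body weight receiving 25.5 % / 27 % of cardiac
output) and an exemplar hydrophobic chemical (PC_liver = 1.5, PC_others =
3 L/kg, ER_liver = 0.7) dosed at 100 mg/min for 200 min followed by
200 min of depuration.

## Worked example

```python
import pbpksim as p

model = p.build_reference_model("man")     # blood + liver + others
scenario = p.default_scenario()            # 100 mg/min, 0–200 min, simulate to 400 min
result = p.simulate(model, scenario)       # stiff BDF, events at 0 and 200 min

ss = p.steady_state_infusion(model, 100.0)
print(p.mass_balance_report(result))       # 5.456968210637569e-16
```

Printed quantities from this run and what they mean:

* `C_blood(200 min) = 58.476 mg/L` — blood concentration at the end of the
  infusion; still rising toward the steady state.
* `C_blood(400 min) = 16.771 mg/L` — after 200 min of depuration the body
  burden has decayed by hepatic extraction.
* steady state `{'blood': 86.188, 'liver': 38.785, 'others': 258.565}` —
  the closed form 100 / (1.6575 × 0.7) = 86.188 mg/L in blood, with the
  lumped tissue at PC_others × C_blood_ss.
* mass-balance residual `5.5e-16` — |Σ amounts + eliminated − dosed|
  relative to cumulative dose, at every one of the 401 output points.

From a shell:

```sh
pbpksim simulate --model builtin:man --out-dir out/
# wrote out/results.csv (401 rows); mass-balance residual 5.46e-16; log out/run_log.json
pbpksim export-sbml --model builtin:man --sbml-out man.xml --round-trip-check
pbpksim validate --model builtin:woman
```

`simulate` writes the results table (time, amounts, concentrations,
cumulative dosed/eliminated), a concentration-vs-time figure, and a run
log with solver, tolerances and package version so the run is repeatable
from the log alone.

## Layout

* `pbpksim.model` — domain types, ODE right-hand side, validation
* `pbpksim.physiology` — reference parameter sets and derivation formulas
* `pbpksim.simulate` — event-aware stiff integration, steady state, audit
* `pbpksim.sbml` — SBML L3V2 writer/reader and consistency checker
* `pbpksim.reporting` — metadata checklist, naming linter, results tables
* `pbpksim.config` / `pbpksim.cli` — configuration files and the CLI

See `docs/methods.md` for modeling assumptions, numerical choices and
limitations.
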