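# Methods

## Model structure and assumptions

The simulator implements a flow-limited (perfusion-limited) compartmental
PBPK model: one well-stirred central blood pool and N well-stirred tissue
compartments, each connected to blood by its perfusion flow. The governing
assumptions are:

* **Well-stirred compartments.** Each compartment has a single
  concentration; intra-tissue gradients are not represented.
* **Flow-limited uptake.** Tissue membranes are not rate-limiting; venous
  blood leaving tissue *i* is at equilibrium C_i / PC_i with the tissue.
  Diffusion-limited kinetics are out of scope.
* **Linear, first-order elimination.** An eliminating organ removes
  Q_i · ER_i · C_blood per unit time. There is no saturable
  (Michaelis–Menten) component, so the whole system is linear in the state
  and superposition holds. Clearance equals Σ Q_i ER_i (L/min) times blood
  concentration.
* **Intravenous input only.** Dosing enters the blood compartment directly
  as a piecewise-constant infusion; oral, dermal and inhalation routes are
  out of scope.
* **Mass, not concentration, as state.** The ODEs are written on amounts
  (mg); concentrations are algebraic outputs (blood mg/L, tissues mg/kg).
  This keeps the conservation audit exact and mirrors how the model is
  exchanged in SBML (species amounts + assignment-rule concentrations).
* **Blood density convention.** Blood weight equals blood volume
  numerically (1 kg/L). Reported blood densities span roughly 0.99–1.06
  g/mL; the unit convention keeps both fields so a model that distinguishes
  them remains expressible.

The dosing window is treated as closed at both endpoints (the boundary
instants count as dosed). The choice is numerically immaterial — a measure-
zero set — but is fixed for determinism.

## Reference physiology and exemplar chemical

The packaged adult parameter sets are:

| input | man | woman | units |
|---|---|---|---|
| body weight BW | 73 | 60 | kg |
| blood volume V_blood | 5.3 | 3.9 | L |
| cardiac output QC | 6.5 | 5.9 | L/min |
| liver weight fraction | 0.026 | 0.026 | of BW |
| liver flow fraction | 0.255 | 0.270 | of QC |

Derived values (liver weight 1.898 / 1.56 kg, remainder 65.802 / 54.54 kg,
liver flow 1.6575 / 1.593 L/min, remainder flow 4.8425 / 4.307 L/min) are
stored unrounded; closure (weights sum to BW, flows to QC) therefore holds
to machine precision by construction. A separate formatter renders each
value at its published precision — 3 significant figures with trailing
zeros kept, except the woman's remainder weight whose exact value 54.54 is
rendered in full; the per-cell rule mirrors the published table rather than
imposing one convention.

The exemplar chemical (PC_liver 1.5, PC_others 3 L/kg, ER_liver 0.7) is a
hypothetical hydrophobic, high-hepatic-clearance compound; partition
coefficients above 1 reflect preferential accumulation in fattier tissue.
These are illustrative defaults, overridable per substance. The default
exposure is 100 mg/min for 200 min followed by 200 min of depuration, with
all compartments starting at 0 mg.

Validation tolerances: models built from the derivation formulas must
close to relative 1e-9; user-supplied models are accepted at relative
1e-3, because published tables print rounded values (a liver weight
printed as 1.90 kg closes only approximately against BW = 73 kg).

## Numerical integration

The infusion makes the right-hand side discontinuous in time, so the
solver integrates **segment-wise** between the exposure boundaries — the
discontinuity is never inside a solver step and no event-detection
heuristics are needed. Within each segment the system is linear with a
constant input, integrated by SciPy's BDF method (stiff-capable, analytic
Jacobian supplied) at default tolerances rtol 1e-8, atol 1e-10 mg. The
tolerances, method and maximum step are exposed as options; DOP853 at
equal tolerance reproduces the stiff solution (the reference system is
only mildly stiff — its time constants span minutes to a few hours).

Cumulative eliminated mass is integrated as an augmented state (the
integral of the clearance rate) rather than by post-hoc quadrature;
cumulative dosed mass has a closed form. Because the sum of the state
derivatives identically equals infusion minus clearance, the conservation
identity is integrated essentially exactly and the audit residual on the
reference run sits at round-off (~1e-16), far below the 1e-6 acceptance
band.

Output is sampled on a uniform grid (default 1 min) with the two event
times always included. Amounts more negative than −1e-9 mg abort the run;
values above that are clipped to zero as round-off.

Problem sizes: the reference run covers 0–400 min at 1-min output (401
points); the steady-state check runs a 10,000-min infusion at 100-min
output, which is ~14 elimination half-lives past any transient and agrees
with the closed form to ~1e-11 relative.

## Steady-state analysis

`steady_state_infusion` solves the linear flow-balance system M·a = −d
(M the exact system matrix, d the infusion vector) rather than using
hard-coded formulas, so it covers any number of eliminating organs. The
closed form C_blood_ss = Dose / Σ Q_i ER_i and C_i_ss = PC_i (1 − ER_i)
C_blood_ss serves as the independent oracle in the tests. A bounded steady
state requires Σ Q_i ER_i > 0; zero total extraction raises an error.

## SBML exchange

Export targets SBML Level 3 Version 2 with a rate-rule dialect: species
are amounts (mg) governed by rate rules, concentrations are assignment-
rule parameters, and the infusion is a `Dosing` parameter toggled by two
events (set to `Dose` when simulation time reaches the exposure start,
back to 0 at the exposure end). Rate rules rather than reactions avoid
inventing stoichiometry for what is natively an ODE model. Every
parameter, species and compartment carries an explicit unit (minute, L,
kg, mg and the derived rate/concentration units, defined from SI base
units).

Identifiers are generic per-tissue (`W_<tissue>`, `Q_<tissue>`,
`PC_<tissue>`, `ER_<tissue>`, `A_<tissue>`, `C_<tissue>`), so round-trip
works for any tissue list; the naming linter also accepts the traditional
spelled-out liver-flow identifier `Q_liver_total`. Numeric values are
serialized with shortest round-trip representation, so re-import
reproduces them bit-exactly, and the re-imported model simulates
identically (parity well below the 1e-6 relative band).

The reader is deliberately narrow: it accepts documents in this dialect
(or structurally equivalent ones) and rejects reaction networks, algebraic
rules, function definitions and initial assignments with an error naming
the first unsupported construct. The writer and the structural consistency
checker (identifier uniqueness, unit resolution, rule/event targets,
declared math symbols) are implemented natively in this package on top of
lxml.

## Reproducibility reporting

The checklist scores only items a machine can decide: model name, code
version, article and code citations, authors with contact details,
license, sources, AI-tools disclosure, units and initial values (carried
by the typed model), attached quantitative results, and the solver/
tolerance record. Items that need human judgement (quality of the model-
purpose statement, conceptual diagram) are emitted as `not-applicable`
with a note and never scored — scoring prose quality would be fake
precision. The score is the fraction of applicable items passed, so
removing satisfied evidence can only lower it.

The naming linter enforces the prefix conventions used throughout the
model surface (`A_`, `C_`, `Q_`, `W_`, `V_`, `PC_`, `ER_` plus a full
lowercase tissue name, and the whole names BW, QC, Dose, `Time_...`),
suggesting a rename where one is mechanically derivable; the suggestions
are themselves conforming, so the linter is idempotent.

## What the defaults do and do not show

All shipped numbers describe reference adults and a synthetic exemplar
chemical. Passing tests demonstrate that the implementation solves the
stated mathematical model correctly (conservation, steady-state agreement,
format round-trips) — they say nothing about predictive validity for any
real chemical: no sensitivity analysis, no parameter estimation, and no
comparison against experimental concentration data are included, and
children, other species, pregnancy and obesity scaling are out of scope.
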