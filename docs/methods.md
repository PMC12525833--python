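# Methods

## Chemical model

All equilibria are written as overall formation reactions
`pM + qL + rH ⇌ MpLqHr` with constants β on the concentration scale in
a constant ionic medium (NaCl). Conventions:

* pH means −log₁₀[H⁺] (free concentration, not activity). Constants
  and pH values are therefore mutually consistent only within one
  (T, I, medium) condition; no activity corrections happen inside the
  solver — ionic-strength transfer is the job of the Debye–Hückel
  module.
* Hydroxo species carry negative r with water autoprotolysis folded
  into β, so `[M₂L(OH)₂] = β·[M]²[L][H]⁻²`. Hydroxide never appears as
  a component; `[OH⁻] = K_w/[H⁺]` enters only the proton mass balance.
* For metal-containing species r is restricted to [−4, +1] (the model
  family used here); ligand protonation species may carry r up to +3
  (LH₃⁺, H₃PO₄).
* Na⁺ and Cl⁻ are spectators unless explicit species (CuCl⁺, ZnCl⁺)
  are declared, in which case Cl⁻ gets its own mass balance.

## Packaged constants and provenance

Every packaged constant carries a source tag:

* `table` — the published potentiometric formation constants of the
  Cu/Zn–PEA/PPC complexes on the grid {15, 25, 37 °C} ×
  {0.15, 0.48/0.49, 0.97 mol L⁻¹}.
* `derived` — auxiliaries reconstructed from the overall/stepwise
  identity log β_aux = log β − log K applied to the published pairs:
  the first PEA protonation constant (from the Zn MLH⁺ row, e.g.
  12.32 − 2.18 = 10.14 at 25 °C/0.15), Cu₂(OH)₂²⁺ (consistently
  −10.72 at 25 °C from both ligand systems), ZnOH⁺ and Zn(OH)₂.
* `external` — literature-style estimates for equilibria the tables
  cannot constrain: the second/third PEA protonation (log K₂ ≈ 5.6,
  log K₃ ≈ 1.2), PPC protonation (log K₁ ≈ 5.7), mononuclear Cu
  hydrolysis (CuOH⁺ ≈ −7.95 at 25 °C, −7.70 at 37 °C), chloride
  complexes (CuCl⁺ log K ≈ 0.2), the biofluid matrix (carbonate,
  phosphate, Ca/Mg side equilibria), penicillamine protonation, and
  the water autoprotolysis values pK_w(T, I) (13.75 at 25 °C/0.15,
  13.37 at 37 °C/0.15, 14.13 at 15 °C/0.15). These were chosen once
  for chemical plausibility; results that lean on them (pL₀.₅,
  distribution landmarks, everything in the fluids module) inherit
  their uncertainty, which is why reports list the active auxiliaries.

## Speciation solver

Unknowns are log₁₀ free concentrations, which enforces positivity and
keeps the Jacobian well-scaled across the >10 orders of magnitude
separating trace metal (10⁻¹² mol L⁻¹) from the medium (10⁻¹). The
Newton iteration uses the analytic Jacobian
`J = ln10·(diag(free) + Nᵀ diag(c) N)` (N the stoichiometry matrix),
steps clipped to one log unit, a backtracking line search, convergence
at 10⁻¹² on the log increments (≤200 iterations), and residuals
reported as max relative mass-balance error (tests require ≤10⁻¹⁰).
Initial guesses are free = total/10³; zero-total components are
eliminated exactly (free = 0). Two fallbacks handle hostile cold
starts: for the full proton balance, a Brent bracketing of the proton
balance over the fixed-pH subproblem (the analytical proton total is
strictly monotone in pH, so the root is unique) followed by a Newton
polish; otherwise a β-continuation ramp. Non-convergence is always
flagged, never silent. For the mononuclear+protonation systems treated
here the equilibrium state is the unique minimum of a strictly convex
Gibbs function, so there are no solution branches to worry about.

## Potentiometry

The cell model is `E = E⁰ + s·log₁₀[H⁺] + j·[H⁺]` with s the
Nernstian slope 0.19841·T(K) mV/decade by default (slopes deviating
>10% are rejected unless explicitly allowed) and j an optional
junction coefficient, default 0. Titrations dilute all totals as
`(C·V₀ + C_t·v)/(V₀+v)`; strong base titrant is entered as an "OH"
stream that decrements the analytical proton total. Electrode
calibration fits (E⁰, pK_w) to a strong acid–base curve via the
closed-form charge balance `[H] − K_w/[H] = C_net(v)`; the alkaline
branch must be present or pK_w is declared unidentifiable.

Constant refinement minimises Σ w_i (E_obs − E_calc)² with w = 1/σ_E²
(σ_E default 0.15 mV); optionally the burette uncertainty is folded in
as an effective variance σ² = σ_E² + (dE/dv·σ_V)², which matters near
equivalence where dE/dv is steep. The Jacobian ∂E/∂log β comes from
implicit differentiation of the mass balances at each solved point
(one small linear solve per point), with Levenberg damping ×10 on
rejection, ÷10 on acceptance. Uncertainties are asymptotic standard
deviations from the weighted normal matrix; the weighted residual
variance is reported and no automatic model selection is attempted —
adding or removing species is the caller's decision.

**Multimodality.** With several strongly correlated constants (a
protonated complex plus two hydroxo complexes, as in Zn–PEA) the
e.m.f. objective from a narrow titration design has genuine local
minima: from a 3-curve design the optimiser can settle ~0.15 log units
off with a ~3 mV RMS misfit. Spanning the full metal:ligand ratio
window (0.33–1) with five designs of ~80 points removes this — which
is why `default_protocols` packages five curves and why real
refinement campaigns titrate at multiple ratios. Users refining ≥3
constants from fewer curves should treat a residual variance ≫ 1 as a
symptom of a secondary minimum.

## NMR fast exchange

Observed shifts are ligand-mole-fraction averages
`δ_obs = Σ q_s [s]/C_L · δ_s` over every ligand-containing species
including the free protonation states; weighting is by the ligand
stoichiometry q (metal-referenced weighting would miscount M₂L
species). Joint refinement is separable: shifts enter linearly and are
solved exactly per outer iteration (variable projection), the outer
nonlinear step adjusts only the free log β values. Species whose
ligand mole fraction never exceeds 10⁻⁴ in the titration window are
rejected as unidentifiable. Inputs are assumed referenced (internal
dioxane handling is a preprocessing concern, not modelled).

## Medium corrections

* z* = Σ(charge²) reactants − Σ(charge²) products, computed from the
  declared charges with H⁺ released by hydroxo species counted on the
  product side; fits accept an explicit z* override because two
  packaged rows print z* values inconsistent with their own fit
  parameters.
* Debye–Hückel fits move the fixed term to the response, leaving
  ordinary linear least squares for (log β⁰, C); unweighted by
  default (a σ-weighted option exists), 95% intervals from the
  t-distribution.
* The van't Hoff expression divides ΔH by R·ln10 (R = 8.314 J K⁻¹
  mol⁻¹, θ = 298.15 K, ΔH in kJ mol⁻¹) — without that divisor the
  equation is dimensionally inconsistent and reproduces no packaged
  magnitude. Valid range 273–373 K; no heat-capacity term.
* ΔG = −RT ln10·log β_θ in kJ mol⁻¹; TΔS = ΔH − ΔG holds exactly by
  construction. One packaged thermodynamic row (Zn–PEA MLOH⁻) violates
  this identity by ~9 kJ mol⁻¹ and is flagged inconsistent in the
  table rather than silently used.

## Sequestration (pL₀.₅)

χ(pL) sums the metal bound in every metal–ligand species, weighted by
metal stoichiometry p, at fixed pH/T/I with the metal at trace.
Defaults: trace metal 10⁻¹² mol L⁻¹ (any value keeping binuclear
species empty gives the same curve — tested by halving), pL grid 1 to
12 in steps of 0.02, chloride at the medium concentration as
background. pL₀.₅ comes from a one-parameter logistic fit over the
full grid, cross-checked against direct interpolation of the χ = 0.5
crossing; both are reported. In the mononuclear trace limit
pL₀.₅ = log₁₀ of the summed conditional constants, which is the
closed-form test oracle.

## Biofluid simulations

Plasma and CSF are treated as externally buffered (fixed pH 7.4,
37 °C, I = 0.15): speciation runs over the full ionic matrix (Na, K,
Ca, Mg, Cl, carbonate, phosphate) with the packaged compositions, and
reports partition total copper into free, inorganic and
ligand-bound shares, both absolute and renormalised over the complexed
fraction. Penicillamine competition converts the 28 µg L⁻¹ dose with
M = 149.21 g mol⁻¹ (overridable) and refuses to run without competitor
protonation constants — a fully deprotonated thiol would overstate its
binding by orders of magnitude.

A caution on interpretation: with dilute-solution mass action and the
packaged constants, binuclear complexes are quadratic in the free
metal and therefore essentially unpopulated at micromolar copper, and
carbonate dominates the inorganic side reactions. The headgroup-bound
copper fractions this module computes at plasma/CSF compositions are
consequently small (≲1%), far below literature figures obtained with
other assumptions; the module asserts physical invariants
(conservation, null controls, dose monotonicity) and reports the
percentages rather than gating on them. Protein binding
(albumin/ceruloplasmin), redox chemistry and kinetics are out of
scope.

## Synthetic data

Generators are pure functions of (inputs, seed) via
`numpy.random.default_rng`; draw order is fixed (volumes, then e.m.f.).
Noise defaults emulate an automated titration bench: σ_E = 0.15 mV,
σ_V = 0.002 mL (applied to the *delivered* volume before the
speciation solve, with the nominal volume recorded — exactly how a
burette error corrupts real data), δ-noise 0.002 ppm. What is *not*
emulated: electrode drift, junction-potential variation, carbonate
ingress, ionic-strength drift along a titration, and NMR lineshape
effects. Passing round-trip and recovery tests therefore demonstrate
estimator correctness and precision at instrument-level white noise,
not robustness to the systematic errors of real titrations.

The packaged per-species NMR shifts are synthetic constructions chosen
so the noiseless free-ligand titrations reproduce the reported
endpoint envelopes (PEA CH₂(1) 4.05→3.73 ppm, CH₂(2) 3.22→2.79 ppm;
PPC CH₂(1) 4.24→4.10 ppm with a pH-invariant N(CH₃)₃ singlet at
3.16 ppm); they are not measured values.

## Known limitations

* No solid phases, no redox (Cu²⁺/Cu⁺), no multi-ligand mixed
  complexes (MLL′), no SIT/Pitzer activity models.
* The `external` auxiliary constants bound the accuracy of every
  conditional quantity; swapping in measured values is a one-line
  change in the constants table.
* Refinement correctness is guaranteed only within the unimodal
  regime discussed above; there is no global optimiser.
* CSV output uses 6 significant digits; byte-stable ordering is by
  species label.
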