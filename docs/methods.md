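# Methods

## The constraint-based model

A metabolic network is held as a stoichiometric matrix **S** (m metabolites
× n reactions). Under the pseudo-steady-state assumption the internal
metabolite concentrations are constant, so feasible flux vectors satisfy
**S v** = 0 with l ≤ v ≤ u. Because n > m the system is underdetermined;
flux balance analysis (FBA) selects a flux vector by maximizing the biomass
pseudo-reaction μ (h⁻¹), a proxy for growth rate. Flux variability
analysis (FVA) then minimizes and maximizes each flux of interest subject
to v_biomass ≥ f·μ* (f ∈ [0, 1]), exposing which fluxes are forced and
which are degenerate.

Conventions:

* **Exchange reactions** are single-metabolite extracellular drains
  (`met_e →`). Uptake is the negative flux direction; a `Media` object
  stores uptake *magnitudes* that are applied to exchange lower bounds.
  Applying a media closes every unlisted exchange for uptake and leaves
  secretion open. Media definitions are organism-independent: entries for
  exchanges a model lacks are ignored (a strict mode raises instead).
* **Boundary species** (SBML `boundaryCondition=true`) are exempt from the
  steady-state constraint. The lumped biomass product is modelled this
  way, which keeps the biomass reaction an ordinary network column while
  letting it carry flux.
* **Default bounds** where a file is silent: reversible −1000/1000,
  irreversible 0/1000 mmol·gDW⁻¹·h⁻¹.
* **Degeneracy.** Only objective values and FVA ranges are contract-stable;
  individual fluxes of a degenerate optimum are not, and the test suite
  never asserts them unless FVA proves them forced. An ATP maintenance
  demand, when a model declares one, is simply a fixed lower bound on that
  reaction; no default is invented.

The LP backend is `scipy.optimize.linprog` (HiGHS) behind a single
maximize-c·v interface, with a primal feasibility tolerance of 1e−9. In
FVA the biomass constraint is relaxed by an absolute 1e−9 (plus 1e−9
relative) so the fixed-optimum subproblems remain numerically feasible.

## Curation audits

* **Elemental/charge balance.** Reaction tallies are computed from Hill
  formulas by exact integer arithmetic. Exchanges (matter crossing the
  system boundary) and the biomass pseudo-reaction (lumped product) are
  exempt. Wildcard formulas (R/X/*, or empty) make a reaction *skipped*,
  not violating — mixed-annotation models are the norm. Charge is tallied
  only when every participant carries a charge.
* **Blocked-exchange test.** With every exchange closed in both directions
  a sound network can produce neither biomass nor free ATP; a positive
  optimum flags a futile, energy-generating loop. Growth below 1e−6 counts
  as zero.
* **Nutrient requirement.** Growth must vanish when all carbon or all
  nitrogen sources are removed from an otherwise complete medium.
* **Directionality.** Report-only: reversible reactions whose reverse
  direction is unusable at the growth optimum are listed as candidates for
  manual tightening; nothing is flipped automatically.

## The atrazine pathway

The hydrolytic route is encoded as a balanced, injectable reaction set:

    TrzN : atrazine + H2O → hydroxyatrazine + Cl⁻ + H⁺
    AtzB : hydroxyatrazine + H2O → N-isopropylammelide + ethylamine
    AtzC : N-isopropylammelide + H2O → cyanuric acid + isopropylamine
    ETHAM_DEAM : ethylamine + H2O + H⁺ → acetaldehyde + NH4⁺ + H2
    IPA_ALA    : isopropylamine + 2 H2O → L-alanine + 3 H2

plus atrazine uptake and cyanuric-acid export. Cyanuric acid is a dead
end: the ring is not cleaved, so one mole accumulates per mole of atrazine
degraded, and the bioavailable yield is 5 C and 2 N per atrazine. Design
choices:

* The amine catabolism steps are **lumped net conversions**. The true
  routes are multi-step and O2/cofactor dependent; these reactions are
  deliberately cofactor-neutral, releasing the reducing equivalents as
  secreted H2 so that elemental and charge balance close without
  committing to a specific electron acceptor. The H2 stream is a
  bookkeeping device, not a physiological prediction.
* Deaminated nitrogen leaves as NH4⁺ (ammonium is a by-product of
  degradation and may be re-consumed); chloride leaves as Cl⁻ + H⁺.
* Injection reuses host metabolites only when formulas agree, so the
  pathway's balance proof transfers to the combined model.

## Dynamic simulation

Discrete ticks of length Δt (default 1 h):

1. finite starting pools per exchange (`math.inf` marks non-depletable
   mineral ions; unlisted exchanges start at 0 — closed for uptake but
   accumulating secretions);
2. per-cell uptake bound min(cap, pool/(X·Δt)) with cap = 1 unit per
   biomass unit per tick by default — the pool-division term makes
   overdraw impossible, so pools are non-negative by construction;
3. pools updated with the realized exchange fluxes times X·Δt;
4. biomass updated by forward Euler, X ← X(1 + μΔt); an exponential
   update X·e^{μΔt} is available as a config option.

The run stops when a tick's relative biomass gain falls below `stall_tol`
(default 1e−6, operationalizing "no further increase in biomass") or at
`max_cycles` (default 200). An infeasible tick records μ = 0 and falls
through to the termination test. Pools and caps are in dimensionless
units; mapping to mmol or mg/l is a user-level scale factor that the
simulator deliberately does not guess. Per-exchange cap overrides exist so
that bookkeeping species (water, protons) are not throttled by the
nutrient cap; the packaged examples leave water/protons uncapped and cap
all nutrients at 1.

Defaults mirror the standard screening conditions: pools of 50 units,
cap 1, one initial biomass unit, Δt = 1.

## Media design

* **Supplement screen**: one FBA per candidate exchange added to a base
  medium at a shared default bound of 10 (per-candidate bounds can be
  supplied); adding a supplement only relaxes the LP, so μ never drops
  below the base value.
* **Classification**: high ≥ 66 % of the screen maximum, low < 25 %,
  moderate between. The cutoffs are fractions of the maximum, hence
  scale-invariant. With a screen topping out at 13 h⁻¹ the canonical
  amino-acid trio 11.3 / 7.4 / 1.4 h⁻¹ classifies high / moderate / low.
* **Gradient surfaces**: μ over an ascending bound grid for two exchanges;
  monotone along both axes by LP monotonicity.
* **Equimolar-nitrogen dosing**: dose = conc_ref/MW_ref · N_ref/N_target ·
  MW_target, with molecular weights computed from formulas (IUPAC 2021
  atomic weights) unless given explicitly. Rounding convention: nearest
  mg/l for solids and salts, one decimal for liquid amines; the unrounded
  value is always returned alongside. For 30 mg/l atrazine
  (≈0.695 mmol N/l) this gives histidine 36, isoleucine 91.2, methionine
  103.8, NH4Cl 37.2, ethylamine 31.4 and isopropylamine 41.1 mg/l.

## Synthetic fixtures — what they do and do not show

`TOY-1` (5 metabolites, 5 reactions) has the closed-form optimum
μ* = min(g, 2n) for uptake bounds (g, n), and its dynamic trajectory is
reproducible by a hand recurrence (geometric doubling while the cap binds;
final biomass X0 + Y·S0 with unit yield). `TOY-2` adds the downstream
catabolism the atrazine pathway needs (acetaldehyde assimilation
3 acald + 3 H2O → glc + 3 H2, alanine deamination
ala + H⁺ + H2O → NH4⁺ + ½ glc, water/proton/H2/chloride/phosphate
infrastructure, reversible ammonium transport for by-product secretion,
and a 0.1 phosphate term in biomass so phosphate limitation is
expressible). With the pathway injected, atrazine as sole C/N source gives
μ* = (5/6)·uptake exactly. Random fixture networks are linear pathways
over a synthetic element "E" with coefficients chosen to conserve atoms
exactly — balance and the blocked-exchange property hold by construction,
and they are deterministic per seed.

Passing tests on these fixtures demonstrate the correctness of the LP
core, the audits, the tick loop and the bookkeeping — not the biology of
any real reconstruction. The fixtures have none of the scale (thousands of
reactions), degeneracy, annotation noise or gap-filling artifacts of a
genome-scale model; results on a real SBML reconstruction inherit that
model's quality. The test suite cross-checks the LP core against two
independent oracles: brute-force vertex enumeration on networks of ≤ 8
reactions, and cobrapy/GLPK on the pathway-injected toy.

## Problem sizes

Test-suite and acceptance-script runs use the fixture networks (5–26
reactions), a 50-model random audit corpus, and dynamic runs of ≤ 200
ticks; everything completes in seconds on one CPU.

## Known limitations

* No parsimonious FBA, MOMA/ROOM, knockout simulation or gap-filling.
* No kinetics: uptake caps are hard bounds, not Michaelis–Menten rates.
* The dynamic loop is first-order explicit; with Δt = 1 the discretization
  error is one tick's worth of growth near pool exhaustion.
* Charge audit silently degrades to element-only when any participant
  lacks a charge annotation.
* Legacy SBML without an FBC objective requires an explicit
  `objective_id`; there is no silent biomass guess.
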