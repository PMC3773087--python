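# Methods

## Scope and model class

`electroflux` implements constraint-based analysis of current-generating
(anaerobically respiring) metabolism: FBA and FVA over a stoichiometric
model with three designated role reactions — biomass (flux = growth rate,
h⁻¹), donor exchange (acetate) and terminal-acceptor exchange (Fe³⁺, a
proxy for an anode). All fluxes are mmol/gDW/h. The sign convention for
exchanges is positive = secretion, negative = uptake; a donor uptake of
magnitude *u* is imposed as the equality `v = −u` on the donor exchange,
and the respiration rate `v_res` is reported as the *magnitude* of the
acceptor-exchange flux, so the tables show positive respiration numbers.

Growth fixing is an **equality** `v_gr = k·v_gr^max`. This matters: only
under equality fixing does the maximum-respiration column increase as
growth decreases (with a `≥` constraint the k = 0 row would dominate all
others). A `≥` variant can be obtained by fixing bounds manually on the
biomass reaction, but it is not the default.

## LP core

The solver is HiGHS (dual simplex) through `scipy.optimize.linprog`, with
primal/dual feasibility tolerances of 1e−9 — two orders tighter than the
1e−3 resolution of the 3-decimal report tables. The method is fixed so that
repeated runs agree bitwise on objective values. Alternate optima are a
fact of these models: objective values and FVA ranges are the contract;
returned flux *vectors* are single deterministic solutions whose degenerate
coordinates must not be over-interpreted (reports that use them say so).
Degenerate equal optima from the min/max pair of an FVA query can land a
hair out of order; `flux_range` sorts the pair rather than failing.

Classification of FVA ranges uses a tolerance of 1e−6 mmol/gDW/h:
`non_functional` if both endpoints are ≤ tol in magnitude, `constant` if
the width is ≤ tol, else `variable`. The knockout designer's convergence
tolerance is 1e−4 (an order tighter than printed equality at 3 decimals).

## Electron accounting

Degree of reduction `γ = 4C + H − 2O − 3N + 5P + 6S − charge` with
reference states CO₂, H₂O, NH₃, phosphate, sulfate. Electron-carrier
pseudo-metabolites (NADH, menaquinol, reduced ferredoxin, reduced
cytochrome c, the reduced acceptor) declare γ directly on the metabolite;
a metabolite with neither formula nor declared γ renders a reaction
"unscored" rather than raising, and unscored exchanges appear as an
explicit residual row in the gap decomposition so partially annotated
models degrade gracefully. Biomass electron content is computed from the
γ-weighted precursors the biomass reaction consumes, not from an empirical
biomass formula — this keeps conservation exact on the synthetic models.

The secretion ranking excludes γ = 0 species (CO₂, water, protons)
automatically, and excludes the terminal acceptor and its immediate
reduction products by walking the non-exchange reactions that touch the
acceptor metabolite (e.g. the Fe³⁺ reductase, hence Fe²⁺). Ties are broken
lexicographically by metabolite id.

The 1 % flux-variance filter compares `|f_max − f_min|` against
`threshold · max(|f_max|, |f_min|, 1e−6)` per reaction — a symmetric
relative-difference criterion that never divides by zero. "Reference flux"
is genuinely ambiguous for a two-state comparison; this is the package's
resolution of it.

## The synthetic model

The generator emits a ~25–30 reaction Geobacter-like network. Defaults are
the study conditions used throughout: acetate uptake 13.630 mmol/gDW/h,
ATP maintenance 0.45 mmol/gDW/h, biomass drawing 30 acetyl-CoA + 10
pyruvate + 60 ATP per unit growth, leaks = (formate, pyruvate). Structure:

* acetate exchange, proton-symport uptake, ATP-dependent activation to an
  acetyl-CoA lump (declared γ = 8);
* lumped TCA: acetyl-CoA + 2 NAD⁺ + 2 Fd_ox → 2 CO₂ + 2 NADH + 2 Fd_red
  (8 e⁻ per acetate, split evenly between the carriers so that
  ferredoxin-consuming routes have realistic slack);
* redundant acetyl-CoA ↔ pyruvate interconversion — pyruvate dehydrogenase,
  formate-producing pyruvate formate-lyase, ferredoxin-driven pyruvate
  synthase — plus formate dehydrogenase into the quinone pool. The
  synthase/lyase pair forms the formate leak: net Fd_red + CO₂ → formate;
* electron transport: NADH dehydrogenase (2 H⁺ pumped), ferredoxin:quinone
  reductase (non-pumping), cytochrome-c reductase (2 e⁻ per quinol, 2 H⁺
  pumped), 1-electron Fe³⁺ reductase with an Fe³⁺/Fe²⁺ exchange pair;
* ATP synthase (3 H⁺ per ATP), fixed maintenance drain, optional
  ATP-dissipating futile cycle, and a proton leak that dissipates surplus
  proton-motive force;
* energized secretion transporters ("leaks") for formate, pyruvate,
  amino-acid-like lumps (from acetyl units, γ = 8(1+n)) and H₂.

Every internal reaction is element-balanced where formulas exist and
γ-balanced everywhere, so the zero-growth respiration ceiling is *exactly*
8 × uptake = 109.040 mmol/gDW/h at the default uptake — the one number the
toy shares with the published-reconstruction analysis by construction,
since it is forced by electron conservation alone.

**Why leaks are energized.** Each leak transporter consumes a small number
of periplasmic protons per secretion unit, with the per-electron cost
strictly increasing along the leak list (0.02, 0.04, … H⁺/e⁻; jittered but
order-preserving under seeded randomization). Two consequences:

1. The minimum-respiration floor is set by the ATP budget (maintenance +
   acetate activation + growth), which *rises* with growth — reproducing
   the qualitative sweep structure where `v_res_max` falls and `v_res_min`
   rises as `v_gr` grows. Capacity-capped leaks would instead make the
   minimum column fall with growth.
2. At minimum respiration the proton-motive force is fully committed, so
   the leak allocation is a unique cost-ordered optimum rather than a
   degenerate split, making the knockout order deterministic.

The planted knockout order recorded in the ground truth is: carbon-backbone
leaks first (amino-acid lumps by descending γ, then pyruvate — they can dump
an order of magnitude more electrons per unit than the ferredoxin-limited
routes), then ferredoxin-limited leaks (formate, H₂) in ascending cost
order. For leak sets mixing amino-acid lumps with pyruvate the relative
order of the carbon leaks depends on which resource binds and is treated as
heuristic; the recovery tests therefore randomize over
formate/pyruvate/H₂ sets, where the order is provable.

The closed-form growth optimum under the defaults,
`v_gr^max = (12u − 3m)/860` (u = uptake, m = maintenance; derivation in the
test suite), gives 0.18862 h⁻¹ — used as an independent check on the LP.

**What the toy does not emulate:** genome-scale redundancy (hundreds of
reactions and alternate pathways), realistic P/O ratios and proton
stoichiometries, amino-acid biosynthesis detail, gene–protein–reaction
structure, and the published model's specific suboptimal-growth numbers.
Passing tests therefore demonstrate the correctness of the *methods*
(LP/FVA, conservation, the design loop) and the qualitative structure of
the biology, not quantitative predictions for *G. sulfurreducens* beyond
the electron-conservation bound.

## Knockout design

The designer loop: FVA on respiration at the fixed growth; stop when
max − min ≤ tol; otherwise take one minimum-respiration solution, rank
secreted byproducts by electron-weighted secretion flux, and knock out
*all* secretion transporters of the top metabolite in one step (a
metabolite with two carriers would otherwise re-route). It re-solves after
every deletion rather than batching, because each knockout changes which
culprit dominates next. The ranking criterion is the package's design
choice for "determined through iterative FVA": it is deterministic,
grounded in the electron ledger, and recovers the expected
carbon-then-ferredoxin deletion structure; other criteria (e.g. largest
flux, largest range) would not distinguish electron-relevant secretions
from inert ones. If the gap persists but no secreted byproduct carries
electrons, the trajectory returns `converged=False` with a diagnostic
instead of guessing.

Feasible-set shrinkage guarantees the trajectory invariants: each step can
only raise the minimum and lower (or keep) the maximum respiration, and the
design growth rate stays feasible because the biomass equality is part of
every LP.

## I/O and determinism

The native JSON format round-trips models losslessly with sorted ids and
keys; report TSVs print 3 decimals with `#`-prefixed provenance headers
(model content hash, uptake, growth, tolerances), so identical configs give
byte-identical outputs. SBML Level 2/3 is read through libSBML: fbc bounds
or kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters, reversibility-based
defaults of (−1000, 1000)/(0, 1000) otherwise, bounds clamped to ±1000,
COBRA-style `M_`/`R_` id prefixes stripped, compartments mapped to the
two-compartment scheme by name. Role reactions (biomass/donor/acceptor)
come from a sidecar mapping because SBML has no such annotation; the
defaults carry the published reconstruction's names (`agg_GS13m_2`,
`EX_ac(e)`, `EX_fe3(e)`).

## Problem sizes and verification

All shipped analyses run on desk-scale models: the default toy (27
reactions), a 12-reaction minimal chain small enough for exhaustive
vertex enumeration (the independent LP oracle in the test suite), and
seed-randomized variants for the parameter-recovery runs (10 seeds in the
acceptance tests). cobrapy serves as a second independent cross-check for
FBA objectives and FVA ranges on the same networks. The acceptance script
recomputes the zero-growth respiration ceiling from a freshly generated
model at run time.

## Known limitations

* Reports that tabulate single flux vectors (variance, reducing-equivalent
  tables) inherit LP degeneracy in redundant routes; only FVA ranges are
  solver-independent. The redundant pyruvate-route fluxes in particular can
  sit anywhere on a large degenerate interval.
* The designer assumes leaks are closable by transporter deletion; gaps
  caused by internal futile structure (not secretion) are reported, not
  repaired.
* Electron accounting requires formulas or declared γ; unscored species are
  quantified as a residual, never imputed.
* No thermodynamic/loop-law constraints, no gene-level deletions, no
  compartments beyond cytoplasm/extracellular.
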