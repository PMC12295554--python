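# Methods

`cordyflux` implements a constraint-based analysis workflow for a
cordycepin-producing *Aspergillus oryzae* strain: formulating a biomass
objective function from measured cell composition, validating a
genome-scale metabolic model (GSMM) by flux balance analysis (FBA) under
measured uptake rates, locating gene amplification targets by combining
FSEOF with comparative flux analysis, and designing media by single-nutrient
scans and carbon-to-nitrogen (C:N) ratio optimization.  This note records
the models, assumptions, parameters and design choices.

## Flux balance analysis

The metabolic state is a flux vector **v** (mmol gDW⁻¹ h⁻¹) satisfying the
steady-state mass balance *S·v = 0* and bounds *lb ≤ v ≤ ub*, where *S* is
the stoichiometric matrix.  FBA solves max **c**ᵀ**v** with the biomass
reaction as objective; the biomass reaction is normalized to produce 1 g
of biomass per flux unit, so its flux is the specific growth rate µ (h⁻¹).

Conventions and protocol constraints:

* **Exchange reactions** touch exactly one extracellular metabolite; uptake
  is a negative flux, so an uptake limit *u* is `lower_bound = −u`.
* **ATP maintenance** (`m_ATP`) is fixed at 1 mmol gDW⁻¹ h⁻¹ (lb = ub = 1).
  If a loaded model file encodes different maintenance bounds, the file's
  bounds are preserved on read and the discrepancy is logged when the
  protocol constraint is applied.
* **Freely transported small molecules** (CO₂, H₂O, sulfate, ammonia,
  phosphate, O₂) get exchange bounds ±1000, the conventional
  effectively-unbounded sentinel; all other exchanges have uptake closed
  until a scenario opens them, secretion open.
* **P/O ratio** is a *model* property, not a solver feature: the electron
  transport stoichiometry of a model (2.5 ATP per NADH, i.e. per ½ O₂, in
  the bundled network) encodes it; the engine imposes no P/O logic.

**Solver.** HiGHS dual simplex through `scipy.optimize.linprog`, with
primal/dual feasibility tolerances tightened to 1e−9 and no randomized
components, so repeated solves return identical vectors.  Infeasibility and
unboundedness are reported as solution status, not exceptions — both are
legitimate analysis outcomes (e.g. probing whether a medium supports growth).

**Degeneracy control.** FBA optima are typically degenerate, which would
make flux comparisons and fold changes ill-defined.  Every flux vector that
is consumed downstream (scenario comparison, FSEOF trajectories) is made
canonical by a parsimonious second stage: total absolute flux Σ|vᵢ| is
minimized subject to the objective being pinned at its optimum (within
1e−9 relative slack).  The auxiliary LP uses the standard t ≥ |v| splitting.

**GAM fitting.** The growth-associated ATP maintenance (GAM, mmol ATP
gDCW⁻¹) enters the biomass reaction as ATP + H₂O → ADP + Pi per gram of
biomass.  Predicted growth decreases monotonically in GAM, so the value
reproducing a measured µ_max at the measured glucose uptake is found by
bisection (relative tolerance 1e−4 on µ; the implied GAM resolution on the
bundled network is ~0.03 mmol/gDCW).  If even GAM = 0 cannot reach µ_max
the fit fails loudly — the model, not the parameter, is at fault.

## Biomass objective function

Each measured component (g/100 gDCW) with an average monomer molecular
weight (g/mol) contributes a stoichiometric coefficient

    coefficient [mmol/gDCW] = content / avg_mw × 10.

Polymers use monomer-residue weights (anhydroglucose 162.10 for glucan,
N-acetylglucosamine residue 203.20 for chitin), so no water-of-condensation
bookkeeping is added — this matches the published coefficient table.
Nucleic acids split into nucleotide mole fractions from GC content
(G = C = gc/2, A = T/U = (1−gc)/2; 0.47 genomic, 0.51 transcript).
Two rows of the published table do not reproduce from their own printed
inputs: arachidic acid (0.01/265.30×10 = 0.000377, printed truncated as
0.0003) and palmitic acid (0.17/200.32×10 = 0.0085, printed 0.009; the
printed MW is inconsistent with palmitate).  The package recomputes and
documents the discrepancy rather than forcing agreement.

Protein enters through an amino-acid mole-fraction map; the shipped default
profile carries the main-text abundances (Leu 3.82, Arg 3.27, Glu 2.81,
Ser 2.72, Asp 2.53, Val 2.33, Gly/Asn 1.63 g/100 gDCW — the Asp value
interpolates a published 2.72–2.33 range) and a full profile can be
supplied as an override file.  Ash and minerals are not modeled.  GAM is a
parameter of the assembled reaction (see fitting above), never hard-coded.

## Scenario validation and comparative flux analysis

Two scenarios: *wild type* (cordycepin export fixed to 0 — no synthetic
pathway flux) and *producer* (cordycepin export fixed at the measured
specific production rate).  Each sets the measured glucose uptake,
maximizes growth, and reports percent error
|µ_pred − µ_exp|/µ_exp × 100 against the measured rate.

The two canonical flux vectors are compared per reaction:

* relative change |v_p − v_wt| / max(|v_p|, |v_wt|), defined as 0 when both
  fluxes are zero and clipped to [0, 1] (a sign flip would otherwise reach
  2); the *changed* flag uses a 0.95 cutoff;
* Log2FC = log₂((|v_p| + ε)/(|v_wt| + ε)) with pseudo-flux ε = 1e−6
  (10³ × the LP feasibility tolerance).  ε keeps reactions silent in the
  wild type — the entire heterologous branch — finite but top-ranked.

FBA-side amplification candidates are reactions with Log2FC > 2 that carry
both EC numbers and a gene association: a target must be an amplifiable,
annotated enzyme.  The two heterologous pathway steps carry EC numbers but
no gene association and are therefore excluded, as in the engineered-strain
annotation.

## FSEOF

Flux scanning based on enforced objective flux: the product flux is fixed
at 10 evenly spaced levels from its value at the unconstrained growth
optimum (v₀, zero for a costly heterologous product) up to 95% of the
theoretical production maximum; growth is re-maximized at each level with
canonical fluxes.  The 95% cap avoids the degenerate vertex at absolute
maximum production where growth hits zero; both the step count and the
fraction are exposed.  The score is the least-squares slope of reaction
flux against enforced product flux, computed on raw fluxes so that the
product reaction itself scores exactly 1 (an internal calibration check).
A target requires slope > 1 (strict, with a 1e−6 numerical guard), a
strictly increasing trajectory, and no sign change — the latter two guards
follow the original FSEOF formulation and exclude oscillating degenerate
fluxes and reactions whose net direction flips.  Exchange/boundary
pseudo-reactions are never flagged: on any network the water/CO₂ balances
rise steeply with enforced production, and boundary reactions are not
amplifiable enzymes.  Final amplification targets are the intersection of
FSEOF targets and FBA candidates, with genes rolled up as the union of GPR
leaf sets (whitespace-separated gene lists parse as OR — isoenzymes).

## Nutrient scans and C:N optimization

Three regimes: CN-limited (essentials — O₂, phosphate, sulfate — at 1000;
no glucose or ammonia), N-limited (essentials + 1 mmol glucose), C-limited
(essentials + 1 mmol ammonia).  Each candidate nutrient is opened alone at
1000, growth is fixed, cordycepin export maximized; infeasible points are
recorded as flux 0.  The protocol growth fix of 0.5 h⁻¹ is used for
genome-scale models; the bundled toy configuration fixes 0.25 h⁻¹, inside
its feasible range under 1 mmol co-substrate.  Classification: productive
under CN-limitation → dual C+N source; otherwise productive under
N-limitation → nitrogen source; otherwise under C-limitation → carbon
source; else inert.  As an LP-relaxation invariant, adding the co-substrate
can never reduce the production optimum; this is asserted across all scan
points.

The C:N optimizer is a two-stage grid scan standing in for the original
(unpublished) ratio-optimization routine: at each (glucose, ammonia) uptake
pair, maximize growth, fix growth at a fraction of that maximum (default
0.9), maximize cordycepin.  Fixing a *fraction* of the point's own maximum
creates the growth/production trade-off that makes an interior ratio
optimal: more ammonia raises the growth requirement itself, consuming
resources, until production saturates at the ATP-limited plateau.  The
optimum is the grid point of maximal production with ties (within 1e−6)
broken toward lower total uptake, i.e. the cheapest supply achieving the
plateau.  The C:N ratio is computed from metabolite formulas with exact
rational arithmetic (6 C per glucose, 1 N per ammonia).  Polymeric
nutrients are represented by an uptake exchange plus a hydrolysis reaction
(chitosan: a 10-mer hydrolyzed by a chitosanase-style reaction to
glucosamine units; the degree of polymerization is configurable).

## The synthetic toy network

The generator emits a 39-reaction, 34-metabolite, two-compartment network
with the qualitative structure the analyses assume — not the scale or flux
magnitudes of a genome-scale fungal model.  Structure: exchanges for
glucose/ammonia/essentials/CO₂/water plus biomass, cordycepin and four
alternative substrates; lumped glycolysis, pyruvate oxidation + TCA, and
oxidative phosphorylation at P/O 2.5; an oxidative PPP branch (R5P +
2 NADPH) and a reversible transketolase shunt; a one-carbon branch
(formate synthesis → formate–THF ligase) feeding a lumped purine pathway
(R5P + glycine + 2 formyl-THF + 4 NH₃ → adenosine) finished by two
heterologous-style steps to cordycepin; glycerol, aspartate, cysteine
(sulfate assimilation) and nucleic-acid (R5P) biomass precursors; `m_ATP`;
and a GAM-parameterized biomass reaction.  All internal reactions balance
C, N, O, P and S exactly (hydrogen is not tracked; NAD(P)/NAD(P)H pairs
share heavy-atom formulas, so redox bookkeeping cannot unbalance them).

**Closed-form certificate.**  Because carbon routing is tree-like and ATP
is the binding resource on glucose, the optima are linear algebra over the
designed constants, evaluated with exact rationals:

* ATP per glucose fully oxidized: K_glc = (5 + 10·P/O) − 1 = 29
  (3 substrate-level + 2 NADH per G6P through glycolysis; 1 ATP + 4 NADH
  per pyruvate; minus the hexokinase ATP);
* ATP per cordycepin exported: K_cord = 7 direct (4 purine assembly +
  2 formate ligation + 1 phosphorylation) + 7/6 G6P opportunity cost ×
  (5 + 10·P/O) + one pyruvate (for glycine) × (1 + 4·P/O) = 53;
* ATP per gram biomass: D = 259 + GAM = 289 by construction — the glucan
  demand is *derived* from the requested glucose yield (0.1 gDW/mmol at the
  reference uptake of 10), so µ(U, v) = (29·U − m_ATP − 53·v)/D gives
  µ_wt = 1.0 h⁻¹ exactly, a maximum cordycepin flux of 289/53 with growth
  fully diverted to zero, and a trade-off slope of −53/289.

The planted FSEOF ground truth follows from the same accounting: the
formate–THF ligase, formate-supply and oxidative-PPP fluxes equal exactly
2·v_cordycepin (two formylations and 4 NADPH per product), hence slope 2;
the glycine and purine steps equal 1·v (slope exactly 1, excluded by the
strict criterion, as is the product reaction itself); the glycerol branch
scales with µ and shows a negative slope; the transketolase shunt flips
direction and is excluded by the sign-change guard.  The nitrogen economy
(2.52 mmol N per gram biomass, 5 per cordycepin) places the C:N grid
optimum at glucose 10 / ammonia 5.0 — ratio 12.0 — on the default grid:
the ammonia threshold for the production plateau is 4.994, so 5.0 is the
cheapest grid point on the plateau at either default grid resolution.

Certificate values that are *not* closed-form are not asserted numerically:
at the 1000-level supplementation the scan optima saturate the O₂/CO₂
exchange sentinels (±1000), so those points are checked qualitatively
(source classification, monotonicity) only; the xylose/C-limited point is
bound by the 1 mmol ammonia budget far from the caps and is asserted
exactly ((1 − 2.52·0.25)/5 = 0.074).

The random seed jitters only non-binding internal upper bounds (sentinel
1e6 plus up to 1e3); stoichiometry is never randomized, so certificates
remain exact for every seed, and generation is byte-identical for equal
spec + seed.  The generator's biomass demands are yield-anchored design
constants, not literal gram compositions; converting the published
composition table into a biomass reaction is the biomass module's job and
is tested against the printed coefficients separately.

**What the toy does not emulate:** genome-scale redundancy (isoenzymes,
parallel pathways, compartmental duplication), realistic P/metabolite
stoichiometry of nucleotides, proton/charge balancing, regulatory or
kinetic effects, and the scale of real flux magnitudes.  Passing tests on
the toy demonstrate correctness of the *algorithms* under controlled ground
truth, not predictive accuracy on a real fungus; the genome-scale model
remains the target of the full-scale (optional, download-required) checks.

## Numerical choices

* LP feasibility/optimality tolerances 1e−9; parsimonious objective pinned
  within 1e−9 relative.
* Slope strictness guard 1e−6; flux-zero tolerance 1e−9; scan/production
  tolerance 1e−6.
* Bisection: 200 iteration cap (never reached in practice), geometric
  bracket expansion from GAM 50.
* Grid ties broken by total uptake, then ratio, deterministically.
* Degenerate inputs: empty GPR evaluates True (no gene requirement); empty
  models yield 0×0 matrices; a composition with no components and positive
  GAM compiles to a pure ATP-hydrolysis biomass reaction.
* The solver cross-checks use HiGHS dual simplex vs interior point, an
  exhaustive vertex-enumeration oracle on ≤12-reaction instances, and an
  independent COBRA/GLPK route reading this package's SBML output.

## Problem sizes

All bundled analyses are desk-scale by design: the toy network (39
reactions) solves in milliseconds; the full test suite, including 20
vertex-enumeration cross-checks and every pipeline stage, completes in a
few seconds; the acceptance script is pure arithmetic plus one toy solve.
Genome-scale runs (≈1950 reactions) use the same code paths and remain
well within routine LP sizes.

## Known limitations

* No flux variability analysis beyond parsimonious canonicalization; no
  MILP (gene knockouts), kinetics or regulation.
* The C:N optimizer is a documented stand-in for an unpublished routine;
  its growth fraction (0.9) is a modeling choice, exposed as a parameter.
* The "1000 mmol"/"1 mmol" protocol levels are interpreted as uptake-rate
  bounds in mmol gDW⁻¹ h⁻¹ (the protocol text omits the denominator).
* The protocol growth fix of 0.5 h⁻¹ exceeds measured fungal rates
  (µ_max ≈ 0.03 h⁻¹); both that value and in-range values are runnable —
  neither interpretation is asserted.
* SBML support targets Level 3 + FBC v2 with a legacy gene-association
  notes fallback; exotic annotation schemes are ignored with a warning.
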