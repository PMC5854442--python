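# Methods

## Model

The pair model contains two soluble proteins P₁, P₂ and one lipid species
M.  Ten reversible reactions connect nine species (P₁, P₂, M, P₁P₂, MP₁,
P₂M, MP₁P₂, P₁P₂M, MP₁P₂M): protein–protein binding in solution and on the
membrane, and protein–lipid binding of free proteins and of complexes.
Each protein binds a single lipid copy; the membrane is described only by
its area A and its lipid pool, with no spatial structure, curvature, or
composition heterogeneity.  Three of the reactions are two-dimensional
(both partners membrane-anchored); their equilibrium constants are the 3D
constants divided by 2σ, where σ (nm scale) is a thermodynamic property of
each binding pair.  Book-keeping all species in volume units multiplies 2D
constants by V/A, producing the single dimensionless group γ = V/(2Aσ).

Detailed balance requires the same σ for the protein–protein and the two
protein–lipid interactions; unequal values are accepted only behind an
explicit override and make the network-builders raise, since the system
then has no equilibrium steady state.

### Equilibrium theory

Given the free lipid [M]_eq, the enhancement Kₐᵉᶠᶠ/Kₐᴾᴾ follows exactly
from the relation quoted in the README; the package's approximation enters
only through [M]_eq, built as λ-weighted interpolation between:

* **[M]⁰_eq** — the no-complex limit (Kₐᴾᴾ = 0): a single-site binding
  quadratic using a concentration-weighted average protein–lipid constant.
  The average is re-weighted twice with the free (equilibrium) protein
  levels implied by the current root; this refinement costs two quadratic
  evaluations and reduces the worst-case theory error on random
  excess-lipid parameter sets from ~3×10⁻⁴ to below 10⁻⁶.
* **[M]ᶜᵒᵒᵖ_eq** — the all-complex limit (Kₐᴾᴾ → ∞): every pairable
  protein is treated as a two-site complex C = min(P₁₀, P₂₀) binding lipid
  through C+M⇌MC, C+M⇌CM and the γ-scaled second-lipid steps to MCM.  Any
  unpaired protein surplus binds lipid with its own single-site constant
  (this choice preserves lipid conservation; it is validated against the
  network equilibrium run at Kₐᴾᴾ = 10¹⁴ M⁻¹ to 10⁻⁴ relative).  With
  matched totals the lipid balance is a cubic solved by a polynomial root
  finder; otherwise (and as fallback) the monotone mass-balance residual
  is bracketed on [0, M₀].
* **λ** — the complexed fraction out of min(P₁₀, P₂₀), the quadratic root
  of the pair balance at Kₐᵉᶠᶠ evaluated with [M]⁰_eq (single-pass
  definition, the default).  An opt-in self-consistent mode iterates
  λ ↔ Kₐᵉᶠᶠ to relative tolerance 10⁻¹⁰ (max 100 iterations, convergence
  flagged in the result).

All quadratics (free lipid, λ, total complexes) use the cancellation-free
root form 2ac/(b + √(b²−4ac)), stable for association constants up to
10¹⁵ M⁻¹ without log-space evaluation.

With `distinct_lipids=True` each protein targets its own lipid pool; the
two balances are solved independently in the zero-complex limit and by
alternating monotone 1D solves in the cooperative limit.

### Derived observables

Total complexes follow from Kₐᵉᶠᶠ via the pair quadratic;
%complexation = 100·[complex]/min(P₁₀, P₂₀).  The membrane fraction of
complexes is (N−1)/N where N is the numerator of the enhancement relation,
since complex species stand in the ratios 1 : K₁M : K₂M : γK₁K₂M².  The
critical lipid concentration (smallest M₀ with Kₐᵉᶠᶠ ≥ (1−ε)·γKₐᴾᴾ,
default ε = 0.01) is found by geometric bracketing plus Brent root
finding on the monotone enhancement-vs-M₀ curve; no closed form is used.
The σ-fitting routine inverts the enhancement relation for γ, either in
the saturated regime (enhancement = γ) or with supplied stickiness values,
and requires a measured enhancement strictly above 1.

## Rate conversions

Macroscopic 3D on-rates combine intrinsic reactivity and the
diffusion-limited rate 4πσD_tot harmonically; off-rates are kₒₙ/Kₐ in
every dimension, and intrinsic dissociation is dimension-independent
(k_b²ᴰ = k_b³ᴰ), which together give Kₐ²ᴰ = Kₐ³ᴰ/2σ.  The macroscopic 2D
rate uses the steady-state pair theory with screening length
b = √(2A/(π max(N₁,N₂)) + σ²); the log in the diffusive resistance is
natural, and for b/σ − 1 < 10⁻³ the resistance bracket is evaluated by its
series (2/3)q + q²/2 + 2q³/5 in q = 1 − σ²/b², since the closed form
cancels catastrophically there.  Default kinetic parameterization:
k_off = 1 s⁻¹ for every reaction, k_on = k_off·Kₐ capped at the diffusion
limit (k_off rescaled to preserve Kₐ exactly), D³ᴰ = 50 µm²/s and
D²ᴰ = 0.5 µm²/s per species.  Equilibria are therefore independent of the
kinetic choices, which the tests assert.

## Mass-action networks

Reaction networks are built species-first with explicit composition
vectors.  At build time every species is assigned a formation constant by
propagating reaction constants from the free monomers; a species reachable
by two paths with different constants means a cycle violating detailed
balance and raises.  The same formation constants parameterize the
algebraic equilibrium solver: free monomer concentrations are solved from
the conservation equations (Powell hybrid start, then damped fixed-point
polishing to residual <10⁻¹⁴ so that exactness tests are limited only by
float arithmetic), with long stiff integration as a last resort.  Time
courses use LSODA with rtol 10⁻¹⁰ and analytic Jacobian; conservation
drift stays below 10⁻⁹ relative.

Kₐᵉᶠᶠ is measured from a state as [complexes]/([P₁]ᶠʳᵉᵉ[P₂]ᶠʳᵉᵉ) with the
free totals evaluated as direct species sums (P₁ + MP₁ etc.) rather than
by subtraction, avoiding cancellation when complexation is nearly
complete.  Equilibration time is the first time after which the total
complex concentration stays within a band (default 1%) of its final
value — the band is a package choice, exposed as a parameter.

The scaffold model adds a protein S with one site for each of two
lipid-binding proteins P₃, P₄ (which do not bind each other); enumeration
gives 14 species and 20 reactions.  A reaction is 2D (γ-scaled) iff both
reactant complexes carry at least one bound lipid; recruitment from
solution is a 3D search.  The scaffold-mediated effective constant is
defined from simulation output as [bridged triples]/([P₃ not in a
triple]·[S not in a triple]·[P₄ not in a triple]) (units M⁻²), with the
membrane-free system defining the solution reference.  This definition is
a reconstruction and is validated only for internal consistency
(enhancement → 1 without membrane, growth with sub-stoichiometric
scaffold); it is not compared against printed numbers.  Beyond matched
stoichiometry the enhancement falls again (the prozone effect), so the
monotonicity property is asserted only for scaffold ≤ peripheral-protein
concentrations.

## Rule-based stochastic simulation

The Gillespie engine operates on molecule types with named sites and
reversible site–site rules.  Lipids are a population count; a complex
(connected component of the bond graph) is membrane-associated iff it
contains a bound lipid.  Bimolecular propensities are k_on³ᴰ/V per
eligible pair when at least one partner is in solution and k_on²ᴰ/A
(default k_on³ᴰ/2σ) when both are membrane-associated.  Pairs within one
complex are excluded — the non-spatial model cannot judge the geometric
feasibility of ring closure — with an opt-in first-order ring-closure
channel.  Eligible-pair counts are maintained incrementally (free-site
pools split by membrane status, per-rule intra-complex pair sums), so each
event costs O(rules) plus local complex surgery; sampling uses rejection
from raw pools with sub-channel weighting, which is exact.  Trajectories
are reproducible given a seed; replicate runs use distinct seeds, and
state consistency (membership, lipid counts, conservation) can be
re-verified from scratch.

Prebuilt models: the pair system (cross-checked against the ODE network
and, for the pure dimer, against the exact chemical-master-equation
partition sum); trimeric clathrin with three leg sites (any leg binds any
other trimer's leg; the 3×3 site-class pairs share one rate) and three
non-competing adaptor sites, AP-2 with a clathrin site and a PIP2 site;
BAR proteins with a dimer site, a non-competing oligomer site and a lipid
site; and a retromer system (VPS17/VPS5 weak PI(3)P binders bridged to the
strong binder SNX3).  Clathrin trimers are the simulated unit, so
heavy-chain copy numbers are divided by 3 where fixtures are used.

### Simulated conditions and problem sizes

The clathrin experiment uses the in vitro conditions V/A = 9.46 µm, lipid
54,668 µm⁻², clathrin and AP-2 at 0.4 µM, clathrin:AP-2 K_d = 22 µM,
AP-2:PIP2 K_d = 2.86 µM, and clathrin–clathrin K_d swept over 10–100 µM.
Simulations run in a V = 0.25 µm³ compartment (60 clathrin trimers, 60
AP-2, ~1,400 lipids) for 30 s at k_off = 1 s⁻¹ — copy numbers chosen so
concentrations, ratios and equilibrium constants are exactly the stated
conditions while trajectories stay cheap; fractions of polymerized and
membrane-bound clathrin are intensive and insensitive to the compartment
size at this scale.  Nucleation pathways are tallied per leg–leg bond
event by the membrane status of both partners immediately before bonding:
2D membrane-localized dimerization versus direct recruitment of a solution
trimer.

The endophilin solution-oligomerization check uses the measured copy
number (55,621 in 1200 µm³ ≈ 77 nM) in a 10 µm³ compartment with the weak
500 µM oligomer contact; the FCHo1/FCHo2 size-disparity comparison scales
the 3706 : 36,302 copy ratio to 20 : 196 molecules.

## What the generators do and do not emulate

Synthetic inputs reproduce the stated concentrations, affinities,
geometries and lipid densities, and the simulators reproduce equilibrium
and (implicitly diffusion-corrected) kinetics of well-mixed compartments.
They do not emulate spatial gradients, membrane curvature and deformation
feedback, lipid clustering, crowding, competition from unmodelled binders,
or non-equilibrium (ATP-driven) remodeling.  Passing tests therefore show
the thermodynamic and stochastic machinery is correct under well-mixed
assumptions, not that real membranes behave quantitatively this way;
BAR-oligomer results in particular are lower bounds because
curvature-mediated cooperativity is absent.

## Numerical choices and degenerate inputs

* Kₐᴾᴾ = 0 short-circuits λ = 0; a zero protein total gives enhancement 1
  and zero complexes; Kₐᴾᴹ = 0 on either side returns enhancement exactly 1.
* Root selection is always the physical branch: free lipid in [0, M₀],
  complexes in [0, min(P₁₀, P₂₀)]; λ clamped to [0,1] against float drift.
* Flagged nulls (`None`) rather than exceptions mark undefined
  observables: membrane fraction with zero complexes, critical lipid with
  γ ≤ 1 or a non-binding partner, Kₐᵉᶠᶠ with a vanishing denominator,
  screening length with zero surface copies.
* The lipid pool must carry an explicit unit tag (per-area vs per-volume
  or molar); holding it fixed per-area makes results depend on V/A through
  the pool size as well as through γ, so silent guessing is refused.

## Limitations

Single lipid-binding site per protein (multi-PIP2 engagement of AP-2 is
representable only as a reduced free-lipid pool); the interpolated [M]_eq
is approximate in the simultaneous lipid-poor/strong-Kₐᴾᴾ corner (a few
percent, worst near the middle of the λ transition, growing toward
nonphysiologically large V/A); the scaffold effective constant is a
package definition; the stochastic engine is non-spatial, so lattice
geometry, cage closure and curvature are out of scope.
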