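# Methods

## Model representation

A model is a set of compartments (each carrying a pH and an ionic
strength), species and reactions with flux bounds in mmol gDCW⁻¹ h⁻¹.
Charges and hydrogen-atom counts live in a separate thermodynamic table —
one record per species with its standard formation energy ΔfG° (kJ/mol) at
the reference state — so the network topology and its thermodynamic
parameterization can be varied independently.  SBML Level 3 models are read
through cobrapy (fbc bounds and objective); the native tabular dialect
(`compartments.tsv`, `species.tsv`, `reactions.tsv` plus the auxiliary
tables) is what the package writes, because three small TSVs diff cleanly
and can be generated as fixtures.  Exchange and biomass reactions are
pseudo-reactions and are never thermodynamically constrained.

## Physicochemical transforms

Formation energies are adjusted to the simulation conditions as

ΔfG'°ⱼ = ΔfG°ⱼ + N_H(j)·RT·ln(10)·pH − RT·A·f(I)·(z²ⱼ − N_H(j))

with everything in kJ/mol and T the actual simulation temperature in K.
Two ionic terms f(I) are available: extended Debye-Hückel
√I/(1 + B√I) with B = 1.6 mol⁻¹ᐟ² L¹ᐟ² (validity I < 0.1 M) and Davies
√I/(1 + √I) − 0.3·I (validity I < 0.5 M).  Note the two brackets cross
near I ≈ 0.1 M: because B > 1, the Debye-Hückel factor is the *smaller*
one at low I and the larger one above the crossover.  Both vanish at
I = 0, where the transform reduces to the exact pH closed form.

The limiting slope A (mol⁻¹ᐟ² kg¹ᐟ²; 1 kg ≅ 1 L is assumed when mixing A
with B) can be computed two ways:

* **temperature mode** — the quadratic
  A = 1.10708 − 1.54508·10⁻³ T + 5.95584·10⁻⁶ T², giving 1.17585 at
  298.15 K;
* **temperature/salinity mode** — assembled from physical constants,
  A = √(2π N_A ρ_sw) · (F²/(4π ε₀ N_A R))³ᐟ² · (ε_sw T)⁻³ᐟ²,
  the natural-log molal Debye-Hückel slope in SI units, with the solvent
  density ρ_sw from the international one-atmosphere equation of state of
  seawater and the static relative permittivity ε_sw from the
  Malmberg-Maryott pure-water polynomial reduced by Stogryn's
  salinity/normality factor.  At S = 0 this tracks the quadratic within
  0.3 % over 5–40 °C (the acceptance property requires 2 %), which pins
  down the unit convention.  Validity windows (t ∈ [0, 40] °C,
  S ∈ [0, 42] g/kg) are enforced, never silently clamped.

Salinity is linked to ionic strength by the seawater relation
I·ρ = 19.92·S/(1000 − 1.005·S), solved in closed form; at I = 0.25 M and a
bacterial buoyant density ρ = 1.11 kg/L this gives S = 13.74 g/kg, the
value used as the high salinity level of the factorial design (computed at
startup, not hard-coded).

No Gibbs-Helmholtz enthalpy correction is applied when moving from 25 to
37 °C: reference formation energies are used as-is and only the RT factors
and A respond to temperature.  The 25→37 °C variation of ΔfG° itself is
treated as small.  Magnesium complexation, multi-protonation pseudoisomer
distributions and the electrical membrane-potential term of transport
energetics are out of scope; transport reactions see only the
per-compartment pH difference through the species transforms.

Reaction standard energies are stoichiometric sums of the transformed
formation energies, with protons and water excluded from both the sum and
the later concentration terms (the transformed-energy convention already
absorbs pH; including them would double-count).  A reaction is *covered*
only if every non-excluded participant has a known record; exchanges and
biomass are never covered.  Each transform carries a fingerprint of the
conditions it was computed at, and the MILP builder refuses records whose
fingerprint does not match — a cheap guard against mixing conditions.

## The TFA MILP

For each covered reaction the program contains

* a flux split v = v⁺ − v⁻ with v± ∈ [0, v_max], v± ≤ v_max·z±,
  z⁺ + z⁻ ≤ 1 (binary);
* the energy definition ΔrG' = ΔrG'° + RT Σ s_ij ln c_j;
* big-M indicators ΔrG' − K + (K+ε) z⁺ ≤ 0 and −ΔrG' − K + (K+ε) z⁻ ≤ 0,

so forward flux requires a driving force of at least ε and backward flux
the opposite.  Defaults: K = 1000 kJ/mol (dominates any attainable |ΔrG'|
within the concentration window), ε = 10⁻⁴ kJ/mol (strictly positive to
forbid zero-driving-force flux), v_max = 1000 mmol gDCW⁻¹ h⁻¹.
Log-concentrations default to [ln 10⁻⁵, ln 0.02] mol/L, the customary TFA
window.  Two constraint modes narrow them: *default_cofactors* pins a
configurable adenylate trio (ATP 9.6·10⁻³, ADP 5.6·10⁻⁴, AMP 2.8·10⁻⁴ M,
±10 %); *experimental* pins every measured species to 90–110 % of its
measured concentration.  The objective is maximization of the biomass
(objective-reaction) flux; a solved objective below 10⁻⁶ h⁻¹ is
classified "no growth".

The MILP is built on optlang's GLPK interface, which is deterministic, so
runs are reproducible without solver seeds.  When a problem is infeasible
(or feasible only below a required growth), `relax_dg_bounds` rebuilds it
with a non-negative slack per covered reaction that widens ΔrG'°
symmetrically, requires the growth target, and minimizes total slack; the
per-reaction slacks, reported in descending order, localize which energies
block feasibility.  Relaxation returns all-zero slacks exactly when the
unrelaxed problem was feasible at the target.

Two verification routes exist besides the solver: a flux-force consistency
check (every active covered reaction must carry a ΔrG' of opposite sign
and magnitude ≥ ε; zero-flux reactions are unconstrained), and an
exhaustive oracle that enumerates all 2ⁿ forward/backward direction
patterns of the covered reactions with the binaries fixed and takes the
best LP optimum.  Zero flux remains admissible inside either direction, so
on networks where every covered reaction's ΔrG' can be pushed past ±ε —
true of the shipped fixture — the enumeration optimum equals the MILP
optimum exactly.  This equality is asserted in the tests rather than
assumed.

## Factorial harness

The 2⁶ design varies t (25/37 °C), I (0/0.25 M), S (0/13.74 g/kg), the A
mode, the activity-correction method and the concentration mode.  Runs are
numbered 1–64 with the temperature bit varying fastest, then I, S, A mode,
method, concentration mode; the decoding of runs 3, 20, 24, 28 and 52 is
pinned by tests so any drift in the ordering is caught.  Each run builds
its conditions from the levels (salinity recomputed from the ionic
strength relation), transforms the energies, assembles and solves the
MILP; per-run failures are recorded as unsuccessful and never abort the
sweep.

Successful runs are grouped into non-redundant solution classes separately
at the flux and log-concentration levels: two solutions are directly
equivalent when their maximum absolute coordinate difference is ≤ 10⁻⁶
(configurable), and classes are the connected components of that relation
— a single-linkage partition, hence independent of input order.
Restricting the compared coordinates to a mapped subset can only merge
classes, never split them.

## Evaluation

Predicted fluxes are mapped onto reference reactions by a
(gsm_id, mfa_id, sign) table: each reference flux is the signed sum of its
mapped genome-scale fluxes, which handles both lumped reactions and
reactions defined in opposite directions between the two conventions.
Agreement is measured by the sample Pearson r (undefined-on-zero-variance
reported as such); metabolomics comparisons are correlated on log₁₀
concentrations by default since concentrations span decades (configurable
to linear).  Direction calls map a flux to {+, −, 0} with a 10⁻⁹
tolerance; a set of non-redundant solutions yields the union call-set,
rendered "0/+"-style, and a reaction is flagged as a flux-pattern change
whenever the predicted call-set differs from the corrected reference call.

Runs are ranked per criterion descending with average ranks on ties,
after rounding scores to 2 decimals (configurable) so near-identical
correlations tie rather than order arbitrarily.  Concordance between
criterion rankings uses Kendall's W with the standard tie correction,
W = 12S / (m²(n³−n) − m ΣT); the joint score of a run is Σ over criteria
of (n − rank + 1), the simplest scheme that is monotone in each rank and
produces the half-integer rank sums that tied average ranks imply.  The
total joint score is conserved at m·n(n+1)/2 regardless of tie structure.

## Centrality stage

A solved flux distribution induces an oriented subnetwork: reactions with
|v| below tolerance are dropped, backward-running reactions have their
stoichiometry negated, and species left without reactions are removed
(idempotent on an already-oriented network).  Every substrate/product pair
of every oriented reaction becomes one unweighted directed edge, with a
configurable side-compound list (currency metabolites: adenylates,
phosphate, water, redox pairs, CO₂ in the shipped default) excluded from
both roles — stoichiometric coefficients do not weight edges.  PageRank is
computed by dense power iteration with uniform teleportation (damping
0.85), uniform redistribution of dangling-node mass and an L1 convergence
tolerance of 10⁻⁸ within 200 iterations (non-convergence is an error, not
a silent return); an independent implementation (networkx) serves as the
oracle in tests.  The priority report ranks species by score (ties broken
lexicographically), bins them by rank position at the 10/30/50 % quantiles
(ceiling of fraction × n), flags measured species and lists measured
species excluded as side compounds or inactive separately.

## The toy fixture

The generator emits a complete, deterministic study system in ~18
reactions: PTS-style glucose uptake, a hexose-phosphate isomerase, a
PFK/FBPase futile pair, a lumped lower-glycolysis step producing a
pyruvate-like acid with 4 ATP and 2 NADH per hexose-bisphosphate, a branch
point with an efficient substrate-level-phosphorylation route (B1, ΔrG'°
= +8 kJ/mol at I = 0) and a direct route (B2, −22 kJ/mol, written in the
reverse convention to exercise mapping sign correction), fermentative
NADH reoxidation to secreted ethanol and CO₂, adenylate kinase, ATP
maintenance and a 30-ATP biomass reaction.  All non-pseudo reactions are
elementally balanced (asserted at generation); species formulas are
constructed by propagation so the balance is exact.

The branch is the scientific point of the fixture.  B1's participants are
chosen so that Σ s_ij(z²ⱼ − N_H(j)) = +13, giving an ionic shift of about
−10 kJ/mol at I = 0.25 M: at I = 0 the reaction is blocked at every
admissible concentration (the adenylate pinning makes the +8 kJ/mol
standard energy insurmountable), while at I = 0.25 M it is feasible with
≥ 1.8 kJ/mol margin under either correction method, both temperatures,
both A modes and both concentration modes.  The optimum therefore jumps
between two analytically known values — biomass flux 2u/15 with B1 active
versus u/15 through B2 — and the factorial sweep splits into exactly two
flux classes on the ionic-strength bit.  Plain FBA instead finds 2u by
running PFK and FBPase simultaneously backwards (net ADP + Pi → ATP), a
thermodynamically impossible composite that the MILP excludes because the
two ΔrG' values cannot both exceed +ε while summing to the ATP-synthesis
energy.  These closed-form optima are stored in the fixture manifest and
used as oracles by the tests.

The seed jitters formation energies by ±0.05 kJ/mol and measured
concentrations by ±5 % — enough to make seeds distinguishable, small
enough that every engineered margin survives (worst-case jitter on a
reaction energy is ~1 kJ/mol against ≥ 1.8 kJ/mol margins).  Topology,
bounds and formulas are seed-independent, and output files are
byte-identical for a fixed seed.

What the fixture does *not* emulate: genome-scale redundancy (thousands of
reactions, alternate optima), thermodynamic data gaps (every species has a
known formation energy), compartment pH/I asymmetries, measurement noise
in the reference fluxes (they are the exact mapped optimum), and realistic
formation-energy magnitudes for the invented intermediates.  Passing tests
therefore demonstrate correctness of the machinery — transforms, MILP
coupling, sweep, grouping, mapping, centrality — not predictive accuracy
on real organisms.

## Numerical choices

GLPK integrality tolerance is left at its default (10⁻⁶ scale); flux
comparisons use 10⁻⁶, direction calls 10⁻⁹, steady-state residuals are
verified to 10⁻⁹; relaxation slacks below 10⁻⁹ are reported as zero.  The
solution-class tolerance (10⁻⁶) and the rank-rounding precision (2
decimals) are configuration, not constants.  Problem sizes were chosen so
the full suite — including the 64-run sweep, a 20-seed FBA/TFA bound
sweep and the 2¹²-pattern enumeration oracle — completes in well under a
minute.

## Known limitations

Thermodynamic variability analysis, flux sampling and flux-minimization
objectives are not implemented; concentration coupling ignores activity
coefficients of the metabolites themselves (only the formation-energy
transform carries the ionic correction); the enumeration oracle is
exponential and guarded accordingly; and the external genome-scale
reproduction requires the user to supply the SBML file (see
`tests/test_acceptance.py`).
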