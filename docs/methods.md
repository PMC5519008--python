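# Methods

## Model representation

A model is a list of metabolites (id, compartment, elemental composition,
charge) and reactions (id, stoichiometry, flux bounds in mmol/gDW/h),
plus an objective reaction and a medium (exchange id → max uptake).
Compartment is part of metabolite identity: the same chemical species in
two compartments is two metabolites, and inter-compartment transport
reactions are gated and lumped exactly like enzymatic steps, so
compartmentalized models need no special handling.

Stoichiometric coefficients are stored as exact rationals (decimals from
model files snapped with a denominator cap of 10^6). Exactness matters
once subnetworks are collapsed: the lumped reaction is a rational
combination of reaction columns, and the claim that internal
intermediates cancel and elements balance is checked with exact
arithmetic, not within a float tolerance. File I/O (SBML Level-3 FBC and
BiGG JSON) and all LP/MILP solving go through cobrapy/optlang (GLPK
backend); metabolites without a parsable formula are loaded, flagged, and
skipped by elemental audits, which is the realistic treatment of R-group
species in curated GEMs.

## Biomass decomposition

The biomass reaction is split losslessly into three parts:

- **GAM** — the growth-associated maintenance: the largest α such that
  α·(ATP + H2O → ADP + Pi + H) is a sub-stoichiometry of the biomass
  column (α = the minimum matched amount over the five species).
- **Adenylate imbalance** — ATP consumption not matched by ADP
  production. A positive value means the biomass demands net de-novo
  synthesis of adenylate-pool metabolites, which is treated as its own
  synthesis target.
- **Entries** — every remaining coefficient, as a per-gDW demand n_j with
  role consumed (building block) or produced (by-product such as
  diphosphate, which likewise gets its own balancing subnetwork).

Reconstruction of the original biomass column from the three parts is
asserted exact on every parse.

## Minimal subnetworks

Every reaction is split into non-negative forward/backward components
(irreversible reactions keep a backward part fixed at zero by bounds —
uniform treatment simplifies both gating and L1 objectives). Each
non-core reaction i gets a binary z_i and the gate

    F_i + B_i + C·z_i ≤ C.

**Carbon cap C.** Default: carbon atoms of the limiting carbon source ×
its uptake bound (60 for a C6 source at 10 mmol/gDW/h — the condition
used throughout the toy studies), overridable, falling back to a big-M of
1000 when the medium has several or unbounded carbon sources. The
smallest valid big-M tightens the MILP; note the cap genuinely restricts
reactions whose unit flux moves less than one carbon (e.g. a biomass
pseudo-reaction), which is irrelevant during per-target synthesis but is
why the cap is configurable.

**Demand.** v_sink ≥ n_j·μ_max, with μ_max from FBA of the parent model
at the configured medium; for targets outside the biomass (industrial
chemicals) an absolute fallback demand of 1e-3 mmol/gDW/h is used. Toy
studies use demand 1.0.

**Objective and membership.** Maximizing Σz_i closes as many gates as
possible; the subnetwork is exactly the open set {i : z_i = 0}. At a
maximum any needlessly open gate would contradict optimality, so no
flux-based pruning is applied; a member carrying |v| < 1e-9 in the
verification LP is logged as solver slack, not removed. Every returned
subnetwork is re-verified by a plain LP (core + subnetwork + sink), and
optionally by single-deletion minimality checks.

**Enumeration.** After each solution the integer cut Σ_{k∈S} z_k ≥ 1
forces at least one different reaction. `minimal-only` mode stops when
the optimum size exceeds S_min; `up-to-size` continues to a cap.
Discovery order within a size class is solver-dependent; the *set* of
minimal subnetworks is the deterministic, tested artifact. If the target
sink already exists as a gated model reaction, its gate is held open and
it is excluded from membership and size — the sink is problem
infrastructure, not biology.

**Blocked targets** (unreachable from core + medium) surface as a typed
error, as do solver timeouts (carrying the incumbent list).

## Lumping

For one subnetwork at fixed sink demand, minimize Σ_{i∈S}(F_i + B_i) —
net flux over subnetwork reactions only, core fluxes free. The optimum
is a vertex, so flux distributes in fixed stoichiometric proportions
(parallel routes collapse onto one). Alternative L1 optima can exist; an
optional check re-solves with a seeded 1e-7 jitter on the objective
weights and flags the lump as degenerate if a different lump results.

The lump is Σ_i S_·i·v_i / v_sink: coefficients below 1e-6 are dropped,
the rest snapped to rationals with denominator ≤ 48 (falling back to
9-significant-digit floats when no rational fits within 1e-6), and the
target coefficient is exactly +1 (per mol of target, not per gDW — the
printable-equation normalization). Participants must be core
metabolites, the target, or species with a boundary reaction (drained
by-products); any other survivor above tolerance means the flux
distribution was not steady for the subnetwork alone and raises an
error rather than silently shipping an unbalanced lump. Elemental and
charge residuals are computed exactly; deduplication merges lumps with
identical participants and coefficients (tolerance 1e-6), concatenating
provenance.

## Thermodynamic directionality (pre-pass)

Thermodynamics enters as an optional bound-tightening pass, not as
in-MILP Gibbs-energy variables: for each covered reaction the range of
ΔG'(c) = ΔG'° + RT·Σ n_m ln c_m over the metabolite concentration box is
computed in closed form; a direction is admitted iff its extreme minus
the stated uncertainty is exergonic. Returned bounds are intersected
with the model's own (never wider), uncovered reactions pass through,
and an empty data set leaves the pipeline bit-identical to
mass-balance-only mode. This keeps the thermodynamic layer pluggable
and auditable; a full TFA formulation with explicit ΔG variables is out
of scope.

## Yield ranking

Each lump is scored on its own mini model (core + lump + target sink +
boundary reactions of included species). The source uptake is fixed at
the medium bound (10 mmol/gDW/h in all comparisons here) and the C-mol
yield is (C_target·v_sink)/(C_source·uptake), with the *bound* in the
denominator. On a sole carbon source the yield lies in [0,1] by carbon
conservation, and the mini-model yield can exceed the lump's naive
carbon fraction because the core may re-assimilate by-products. Ties
break by lump size, then equation string, making rankings deterministic.

## Reduction

The candidate model is core + every deduplicated lump + parent
transport/exchange reactions touching only included species + biomass +
parent boundary reactions whose species exist in the model. Each
biomass substrate must have at least one supplier, checked at assembly.
Maximal growth μ* is computed, fixed as v_biomass ≥ μ*(1 − 1e-6) (an
inequality with slack, not an equality — MILP numerics), and a binary
per lump gates its flux while Σ binaries is minimized. The pruned model
must re-attain μ ≥ μ*(1 − 1e-4). μ_reduced ≤ μ_GEM always, because the
reduced feasible set is a restriction of the parent's.

## Synthetic fixtures and the oracle

The toy generator plants the ground truth instead of estimating it: a
reversible core chain fed by one C6 source at 10 mmol/gDW/h; per target,
disjoint linear paths of chosen lengths; optionally b balancer steps per
path, where a step sheds a side metabolite whose only consumer is a
dedicated balancing reaction returning it to a core species (the first
path step then consumes 1+b precursor equivalents, so every metabolite's
formula is an integer multiple of one base composition and every
reaction balances exactly); plus dead-end and core-shortcut decoy
reactions. By construction the minimal subnetworks are exactly the
shortest planted paths with their balancers, and the expected lump per
path is {anchor: −(1+b), recycle: +b, target: +1}. Seeds fully determine
the output.

What the toys deliberately do not emulate: cofactor coupling, realistic
GEM degree distributions, shared intermediates between alternative
routes, multi-compartment transport costs, or missing formulas. Passing
the desk-scale suite therefore certifies the *algorithms* (optimality,
enumeration completeness, exact balancing, reduction behaviour) — not
biological conclusions about any organism, which require running the
genome-scale driver on a curated GEM.

The oracle enumerates non-core subsets by increasing cardinality with an
LP feasibility test per subset, implemented on scipy/HiGHS arrays —
independent of the cobrapy/GLPK route it certifies — and returns all
feasible sets at the first feasible size (all inclusion-minimal, since
every proper subset is smaller than the minimum). Intended for
|R^ncGEM| ≤ ~20; the studies keep |R^ncGEM| ≤ 14.

## Problem sizes and numerical choices

The validation studies use 50 seeded fixtures (oracle agreement), 20
(lump soundness, balancer recovery), one two-target reduction toy and
the hand-derivable yield pair — sizes at which exhaustive certification
is exact and the whole study runs in seconds. MILP integrality/
feasibility tolerances are GLPK defaults with binaries rounded at 0.5
before set extraction; demand satisfaction uses relative slack 1e-6;
lump coefficient drop tolerance 1e-6; flux-slack warning threshold 1e-9.
Degenerate inputs: empty subnetworks (core-producible targets) enumerate
to the single empty solution and are not lumped; duplicate sink ids get
deterministic numeric suffixes; unknown identifiers fail fast with the
offending names listed.

## Known limitations

- Alternative L1 optima can yield different (all valid) lumps for one
  subnetwork; only degeneracy *detection* is provided.
- Enumeration cost grows with the number of alternatives; published-scale
  totals on full GEMs are hours of MILP and belong in the opt-in
  benchmark driver, not the test suite.
- The directionality pre-pass is coarser than a full TFA: it cannot
  couple concentrations across reactions, so it admits any direction
  some concentration vector allows per reaction independently.
- Yield records assume a single carbon source; multi-source media have
  no defined C-mol denominator here.
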