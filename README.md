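# lumpnet

Minimal biosynthetic subnetworks and elementally balanced lumped
reactions from genome-scale metabolic models (GEMs).

## The problem

Small "core" stoichiometric models of central carbon metabolism
(glycolysis, pentose-phosphate pathway, TCA cycle, parts of the electron
transport chain) are still the workhorses of metabolic flux analysis and
kinetic modelling, but they need to know what each biomass building block
(BBB) — every amino acid, nucleotide, lipid, cofactor demanded by the
biomass reaction — costs in terms of core precursors, ATP, redox and
nitrogen/sulphur sources. Database pathways are linear and not mass
balanced: they ignore the side metabolites that must also be balanced at
steady state, so they misstate those costs.

lumpnet computes the costs from the GEM itself. For a user-defined core
(metabolites M^core, reactions R^core) and each target metabolite *j* it
solves the mixed-integer linear program

```
maximize    Σ_i z_i                 over non-core reactions i
subject to  S·v = 0
            v_BBB,j ≥ n_j · μ_max
            F_i + B_i + C·z_i ≤ C   (big-M gate, z_i ∈ {0,1})
```

where every reaction is split into forward/backward parts `v_i = F_i −
B_i` with `F_i, B_i ≥ 0`, `n_j` is the biomass coefficient of the target,
`μ_max` the parent GEM's maximal growth rate, and `C` the carbon-atom
uptake flux of the medium (6 × 10 = 60 for glucose at 10 mmol/gDW/h).
`z_i = 1` forces reaction *i* to zero flux regardless of direction, so the
open gates at the optimum form the *smallest* non-core subnetwork S^j
that, together with the core, sustains steady-state synthesis of the
target — including any branches that mass balance forces onto the
"linear" route. Alternative subnetworks follow by integer cuts
(`Σ_{k∈S^j} z_k ≥ 1` after each solution).

Each subnetwork is then collapsed: an L1 flux minimization over the
subnetwork (sink fixed at the demand, core fluxes free) gives a
stoichiometrically proportional flux distribution, and the flux-weighted
sum of the member reactions — normalized to +1 mol of target — is the
**lumped reaction**. All internal intermediates cancel exactly, so the
lump contains only core metabolites, the target and drained by-products,
and its elemental/charge balance is audited to zero. Alternative lumps
are ranked by C-mole yield (carbon in target flux / carbon in source
uptake) on per-lump "mini" models, and a reduced model (core + lumps +
transports/sinks + biomass) is assembled by fixing the maximal biomass
yield and selecting a minimal set of active lumps with a second MILP.

Optional thermodynamic pre-processing turns standard transformed Gibbs
energies and metabolite concentration ranges into tightened reaction
directionality bounds before the MILP.

## Worked example

Models come in through SBML-FBC or BiGG JSON (`lumpnet.load_model`); the
example below uses the built-in toy generator, which plants a known
3-step synthesis path whose second step sheds a side metabolite that only
a dedicated balancing reaction can return to the core.

```python
from lumpnet import (ToySpec, make_toy_gem, split_and_gate, build_problem,
                     enumerate_alternatives, lump_subnetwork, dedupe_lumps)

fx = make_toy_gem(ToySpec(seed=0, n_core_reactions=3,
                          planted_paths=((3, 1),), branch_balancers=1,
                          n_decoys=2))
model, partition = fx.model, fx.partition
target = fx.targets[0]

gated = split_and_gate(model, partition)      # carbon cap C = 6 × 10 = 60
problem = build_problem(gated, target, demand=1.0)
result = enumerate_alternatives(problem, mode="minimal-only")
print(f"target {target}: S_min = {result.s_min}, "
      f"{len(result)} minimal subnetwork(s)")
for sub in result:
    print("  members:", sorted(sub.reactions))
lumps = dedupe_lumps([lump_subnetwork(model, partition, sub, 1.0)
                      for sub in result])
for lump in lumps:
    print("  lump:", lump.equation())
    print("  residuals:", {k: str(v) for k, v in lump.balance_report.items()})
```

prints

```
target TGT0: S_min = 4, 1 minimal subnetwork(s)
  members: ['BAL0_0_0_0', 'P0_0_0_0', 'P0_0_0_1', 'P0_0_0_2']
  lump: 2 M0 -> M2 + TGT0
  residuals: {'C': '0', 'H': '0', 'O': '0', 'charge': '0'}
```

The smallest subnetwork has four reactions: the three planted path steps
plus the mandatory balancer (`BAL…`) — without it the shed side
metabolite accumulates and *no* amount of path flux can make the target.
The lump says one mole of target costs two moles of the core precursor
`M0` and returns one mole of `M2` as a balanced by-product; all elemental
and charge residuals are exactly zero.

The same flow runs from the shell:

```
lumpnet toy --seed 0 --out toy.json --core-out core.yaml
lumpnet subnetworks --model toy.json --core core.yaml -t TGT0 \
    --demand 1.0 --emit-lumps
```

For genome-scale runs (hours per enumeration on a full GEM), see
`scripts/benchmark_paper.py --help`.

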