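# raflsbool

Qualitative modelling of rheumatoid-arthritis fibroblast-like synoviocytes
(RA-FLS) with Boolean networks. RA-FLS drive joint destruction in rheumatoid
arthritis: they secrete inflammatory cytokines, matrix-degrading enzymes and
RANKL, proliferate aggressively and resist apoptosis. `raflsbool` implements
the full qualitative pipeline used to analyse a logical model of this cell
type and to screen drug combinations in silico:

- **Model I/O** — BoolNet `.bnet` text models and the Boolean subset of
  SBML-qual, with the CaSQ input convention (an input is a node whose rule is
  its own variable or a constant).
- **Value propagation** — seed assignments x ∈ {0,1} are substituted into
  downstream rules, rules that become constant fix their node, and the new
  constants propagate until a fixpoint; the reduced model preserves all
  terminal trap spaces.
- **Terminal trap spaces** — subspaces s ∈ {0,1,−1}ⁿ (−1 = free) closed under
  the dynamics: for every fixed node v, fᵥ(x) = sᵥ for all states x in the
  subspace. Inclusion-minimal ("terminal") trap spaces approximate the
  attractors and provide the ON/OFF/unfixed phenotype readout.
- **Asynchronous dynamics** — exact attractors as bottom SCCs of the
  asynchronous state-transition graph, uniform random walks, and per-node
  oscillation statistics (the TP53–MDM2 negative feedback loop).
- **Continuous-time stochastic simulation** — kinetic Monte Carlo (Gillespie)
  over asynchronous flips: node v flips with propensity `rate_up[v]` /
  `rate_down[v]` when its rule disagrees with its value; ensembles of
  trajectories give time-dependent activation probabilities P(v = 1 at t).
- **Screening** — literature scenarios, knockout matrices, drug screens
  (drugs = clamp sets), breadth-first minimal drug-combination search and
  cell-type specificity counts.

The package ships a 53-node fixture model of the RA-FLS logic (17 inputs,
a shared signalling core, five phenotype nodes) in two variants: the
*modified* model, in which caveolin-1 is a dominant-negative regulator of
apoptosis (`Apoptosis = !CAV1_rna & (CASP3 | CASP8 | TNFRSF10A | TNFRSF10B)`),
and the *original* OR-form variant, plus a scenario library and a drug-target
table.

## Worked example

```python
from raflsbool import (fixture_rafls, inputs_of, mutate,
                       terminal_trap_spaces, propagate)

net = fixture_rafls()                 # 53 nodes, 17 inputs, 5 phenotypes
res = propagate(net, {"IL6_Extracellular_space": 1})
print(res.fixed["Inflammation_phenotype"])   # -> 1

working = net
for v in inputs_of(net):              # fully inflamed condition
    working = mutate(working, v, 1)
(space,) = terminal_trap_spaces(working)
print(sorted(v for v, b in space.items() if b == -1))
# -> ['BAX', 'CASP9', 'MDM2', 'TP53']
```

The first result says IL-6 alone forces inflammation ON even with every
other input left free. The second says that with all inputs active the model
has a single terminal trap space whose only unfixed nodes are the TP53–MDM2
feedback motif and its mitochondrial targets — exactly the nodes that
oscillate in asynchronous simulation.

Running `python examples/03_stochastic_probabilities.py` prints the
continuous-time endpoint probabilities (5000 trajectories, t = 40):

```
P(Inflammation | IL-6)          = 1.0
P(Proliferation | PDGFA)        = 1.0
P(Bone erosion | SFRP5, !RANKL) = 0.0
P(Matrix degr. | MMP1 KO)       = 0.0
P(Apoptosis | FASLG, original)  = 1.0
P(Apoptosis | FASLG, modified)  = 0.0
```

The apoptosis contrast is the point of the modified rule: under the original
OR logic any extrinsic signal activates apoptosis, whereas with CAV1 dominant
(MIR192 off) apoptosis stays OFF — the apoptosis-resistant RA-FLS phenotype.
`examples/04_drug_screen.py` screens the packaged drug table under the
inflamed baseline (all inputs ON, MIR192 OFF) and recovers the minimal
six-target combinations (CAV1 + IL-6 axis + IL7 + FOS *or* JUN + MMP3 +
CREB1) that switch all five phenotypes to the therapeutic objective.

Each script in `examples/` is a short narrative of one capability; the
`raflsbool` console command exposes the same operations from a shell
(`raflsbool validate`, `propagate`, `trapspaces`, `walk`, `simulate`,
`scenarios`, `screen`, `combos`, `module`, `specificity`).

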