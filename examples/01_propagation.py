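"""Value propagation: which signals are sufficient to fix a phenotype.

Loads the packaged RA-FLS fixture model and propagates single-input
assignments through the logic to see what they force downstream.
"""

from raflsbool import fixture_rafls, inputs_of, propagate

net = fixture_rafls()
print(f"model: {len(net.nodes)} nodes, {len(inputs_of(net))} inputs, "
      f"{len(net.phenotypes)} phenotypes")

# IL-6 alone: every other input left free, yet inflammation is forced ON
res = propagate(net, {"IL6_Extracellular_space": 1})
print("IL-6 active ->", "Inflammation_phenotype =",
      res.fixed["Inflammation_phenotype"])

# TNF alone (all other inputs off) fails; adding the NFKB complex succeeds
quiet = {v: 0 for v in inputs_of(net)}
res = propagate(net, {**quiet, "TNF": 1})
print("TNF alone   ->", "Inflammation_phenotype =",
      res.fixed["Inflammation_phenotype"])
res = propagate(net, {**quiet, "TNF": 1, "IKBA_NFKB_RELA": 1})
print("TNF + NFKB  ->", "Inflammation_phenotype =",
      res.fixed["Inflammation_phenotype"])

print("\nReading: 1 = phenotype forced ON, 0 = forced OFF. IL-6 is a "
      "sufficient inflammation signal; TNF needs the IKBA/NFKB/RELA complex.")
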