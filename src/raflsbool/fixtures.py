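"""Packaged fixture models and generators.

``fixture_rafls`` is a 53-node emulation of the RA-FLS signalling logic at
desk scale: 17 experimental-condition inputs, a shared regulatory core and
the five phenotype sink nodes (inflammation, apoptosis, bone erosion,
matrix degradation, cell growth/survival/proliferation). It encodes the
qualitative behaviours the full model exhibits — IL-6 sufficient for
inflammation while TNF/IL-17 additionally require the IKBA/NFKB/RELA
complex; the Wnt/SFRP5 and RANKL/IL-7 control of bone erosion; MMP-driven
matrix degradation gated by MMP3; PDGFA-driven proliferation through
CREB1/YWHAQ; and the apoptosis rule in which CAV1 acts as a
dominant-negative regulator, itself inhibited by MIR192. The TP53–MDM2
negative feedback loop (with the BAX/CASP9 mitochondrial arm) is wired so
that, with every input active, exactly those four nodes stay unfixed and
oscillate.

Two deliberate modelling choices (documented in the methods note): NFKB
activity feeds inflammation through endogenous IL-6 production, which
reconciles "TNF needs NFKB" with "blocking the IL-6 axis alone silences
inflammation"; and MMP1/MMP9 require MMP3 (pro-enzyme activation), giving
MMP3 complete control over matrix degradation.

``fixture_rafls_unmodified`` differs in exactly one rule: apoptosis uses
the original OR form in which the CAV1 inhibitor is not dominant.
"""

from __future__ import annotations

import importlib.resources
from typing import List

import numpy as np

from .bnet import parse_bnet
from .expressions import Const, Not, Var, make_and, make_or
from .network import BooleanNetwork
from .screening import DrugSpec, Scenario, load_drugs

__all__ = [
    "INPUT_NODES",
    "PHENOTYPE_NODES",
    "fixture_rafls",
    "fixture_rafls_unmodified",
    "scenario_library",
    "random_network",
    "packaged_drugs",
]

INPUT_NODES = (
    "IL6_Extracellular_space",
    "TNF",
    "IL17A",
    "FASLG",
    "PDGFA",
    "MIR192",
    "SFRP5",
    "WNT1",
    "TNFSF11",
    "IL7",
    "IKBA_NFKB_RELA",
    "DNA_damage",
    "AKT2",
    "proMMP1",
    "proMMP9",
    "TNFRSF10A_rna",
    "TNFRSF10B_rna",
)

PHENOTYPE_NODES = (
    "Inflammation_phenotype",
    "Apoptosis_phenotype",
    "Bone_Erosion_phenotype",
    "Matrix_Degradation_phenotype",
    "Cell_Growth_Survival_Proliferation_phenotype",
)

_APOPTOSIS_MODIFIED = (
    "!CAV1_rna & (CASP3_phosphorylated | CASP8 | TNFRSF10A_rna | TNFRSF10B_rna)"
)
_APOPTOSIS_ORIGINAL = (
    "!CAV1_rna | CASP3_phosphorylated | CASP8 | TNFRSF10A_rna | TNFRSF10B_rna"
)

_FIXTURE_TEMPLATE = """\
targets, factors
# --- inputs (self-rules: value = experimental condition) ---
IL6_Extracellular_space, IL6_Extracellular_space
TNF, TNF
IL17A, IL17A
FASLG, FASLG
PDGFA, PDGFA
MIR192, MIR192
SFRP5, SFRP5
WNT1, WNT1
TNFSF11, TNFSF11
IL7, IL7
IKBA_NFKB_RELA, IKBA_NFKB_RELA
DNA_damage, DNA_damage
AKT2, AKT2
proMMP1, proMMP1
proMMP9, proMMP9
TNFRSF10A_rna, TNFRSF10A_rna
TNFRSF10B_rna, TNFRSF10B_rna
# --- regulatory core ---
CAV1_rna, !MIR192
NFKB_act, IKBA_NFKB_RELA & (TNF | IL17A)
IL6_endogenous, NFKB_act
IL6R_sig, IL6_Extracellular_space | IL6_endogenous
JAK1, IL6R_sig
STAT3, JAK1
IRF1, STAT3
IRF5, STAT3
IRF7, STAT3
CASP8, FASLG | TNF
BID, CASP8
BAD, TNF
BCL2, AKT2 & !BAD
TP53, DNA_damage & !MDM2
MDM2, TP53
BAX, TP53 & !BCL2
CASP9, BAX & !BCL2
CASP3_phosphorylated, CASP8 | CASP9
CTNNB1, WNT1 & !SFRP5
MAPK14, TNF | IL17A
FOS, MAPK14
JUN, MAPK14
AP1, FOS & JUN
NFATC1, TNFSF11 & IL7
MMP3, NFKB_act | STAT3
MMP1, proMMP1 & MMP3
MMP9, proMMP9 & MMP3
CREB1, PDGFA | TNF
FOXO1, PDGFA | TNF
YWHAQ, FOXO1
RPS6KB1, PDGFA
# --- phenotype sinks ---
Inflammation_phenotype, IRF1 & IRF5 & IRF7
Apoptosis_phenotype, {apoptosis}
Bone_Erosion_phenotype, CTNNB1 | NFATC1 | AP1
Matrix_Degradation_phenotype, MMP1 | MMP9
Cell_Growth_Survival_Proliferation_phenotype, CREB1 & YWHAQ & (RPS6KB1 | MAPK14 | NFKB_act)
"""


def fixture_rafls() -> BooleanNetwork:
    """The fixture model with the modified (CAV1-dominant) apoptosis rule."""
    return parse_bnet(_FIXTURE_TEMPLATE.format(apoptosis=_APOPTOSIS_MODIFIED))


def fixture_rafls_unmodified() -> BooleanNetwork:
    """The fixture model with the original OR-form apoptosis rule."""
    return parse_bnet(_FIXTURE_TEMPLATE.format(apoptosis=_APOPTOSIS_ORIGINAL))


def scenario_library() -> List[Scenario]:
    """The packaged validation scenarios (qualitative literature conditions).

    Scenarios flagged ``known_conflict`` encode expectations the model misses
    without an additional model condition (activation of the IKBA/NFKB/RELA
    complex); their ``resolved_by`` counterpart adds it and scores 1.
    """
    I, A, B, M, P = PHENOTYPE_NODES
    return [
        Scenario(
            "IL6_ON",
            inputs={"IL6_Extracellular_space": 1},
            expected={I: 1},
            citation="IL-6 alone suffices to activate inflammation",
        ),
        Scenario(
            "TNF_alone",
            inputs={"TNF": 1},
            expected={I: 1},
            citation="TNF is a major inflammation pathway, but the model "
            "requires the IKBA/NFKB/RELA complex in addition",
            known_conflict=True,
            resolved_by="TNF_plus_NFKB",
        ),
        Scenario(
            "TNF_plus_NFKB",
            inputs={"TNF": 1, "IKBA_NFKB_RELA": 1},
            expected={I: 1},
            citation="TNF activates inflammation once the NFKB complex is active",
        ),
        Scenario(
            "IL17_alone",
            inputs={"IL17A": 1},
            expected={I: 1},
            citation="IL-17, like TNF, needs the NFKB pathway",
            known_conflict=True,
            resolved_by="IL17_plus_NFKB",
        ),
        Scenario(
            "IL17_plus_NFKB",
            inputs={"IL17A": 1, "IKBA_NFKB_RELA": 1},
            expected={I: 1},
            citation="IL-17 activates inflammation once the NFKB complex is active",
        ),
        Scenario(
            "PDGFA_proliferation",
            inputs={"PDGFA": 1},
            expected={P: 1},
            citation="PDGF is an essential fibroblast mitogen",
        ),
        Scenario(
            "WNT_bone_erosion",
            inputs={"WNT1": 1, "SFRP5": 0},
            expected={B: 1},
            citation="without SFRP5 the canonical Wnt pathway drives bone erosion",
        ),
        Scenario(
            "SFRP5_blocks_bone_erosion",
            inputs={"SFRP5": 1, "TNFSF11": 0},
            expected={B: 0},
            citation="SFRP5 active and RANKL absent deactivate bone erosion",
        ),
        Scenario(
            "IL6_proMMP1_matrix_degradation",
            inputs={"IL6_Extracellular_space": 1, "proMMP1": 1},
            expected={M: 1},
            citation="MMP1 activation degrades the cartilage matrix",
        ),
        Scenario(
            "MMP1_KO_matrix_degradation",
            inputs={"IL6_Extracellular_space": 1, "proMMP1": 1},
            mutations={"MMP1": 0},
            expected={M: 0},
            citation="matrix degradation is lost when MMP1 is knocked out",
        ),
        Scenario(
            "FASLG_AKT2_BIDKO_apoptosis_modified",
            inputs={"FASLG": 1, "AKT2": 1, "MIR192": 0},
            mutations={"BID": 0},
            expected={A: 0},
            citation="with CAV1 dominant (MIR192 off), apoptosis stays off "
            "despite FASLG",
            variant="modified",
        ),
        Scenario(
            "FASLG_AKT2_BIDKO_apoptosis_unmodified",
            inputs={"FASLG": 1, "AKT2": 1, "MIR192": 0},
            mutations={"BID": 0},
            expected={A: 1},
            citation="the original OR rule lets FASLG activate apoptosis",
            variant="unmodified",
        ),
        Scenario(
            "all_inputs_active",
            default_inputs=1,
            expected={I: 1, A: 1, B: 1, M: 1, P: 1},
            citation="fully inflamed condition; the TP53-MDM2/BAX/CASP9 motif "
            "stays unfixed and oscillates",
        ),
        Scenario(
            "CAV1_KO_apoptosis",
            mutations={"CAV1_rna": 0},
            inputs={"MIR192": 0},
            default_inputs=1,
            expected={A: 1},
            citation="inhibiting CAV1 re-enables apoptosis in the inflamed state",
        ),
    ]


def packaged_drugs() -> List[DrugSpec]:
    """The shipped drug-target table (targets restricted to fixture nodes,
    plus a few deliberately absent targets exercising the skip path)."""
    ref = importlib.resources.files("raflsbool").joinpath("data/drugs.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_drugs(path)


def random_network(
    n_nodes: int, n_inputs: int, max_indegree: int, seed: int
) -> BooleanNetwork:
    """Random Boolean network generator for property-based testing.

    The first ``n_inputs`` nodes are self-rule inputs; every other node gets
    a random AND/OR/NOT expression over at most ``max_indegree`` distinct
    regulators. Deterministic for a given seed.
    """
    if n_inputs > n_nodes:
        raise ValueError("n_inputs must not exceed n_nodes")
    if n_nodes < 1 or max_indegree < 1:
        raise ValueError("n_nodes and max_indegree must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n_nodes)]

    def random_expr(regs: List[str]):
        if len(regs) == 1:
            leaf = Var(regs[0])
            return Not(leaf) if rng.random() < 0.4 else leaf
        split = int(rng.integers(1, len(regs)))
        left = random_expr(regs[:split])
        right = random_expr(regs[split:])
        op = make_and if rng.random() < 0.5 else make_or
        expr = op([left, right])
        return Not(expr) if rng.random() < 0.15 else expr

    rules = {}
    for i, name in enumerate(names):
        if i < n_inputs:
            rules[name] = Var(name)
            continue
        k = int(rng.integers(1, max_indegree + 1))
        regs = list(rng.choice(names, size=min(k, n_nodes), replace=False))
        rules[name] = random_expr(regs)
    return BooleanNetwork(names, rules)
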