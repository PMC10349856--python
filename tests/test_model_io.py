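"""Model I/O: .bnet parsing/serialisation, SBML-qual, structural operations."""

import pytest

from raflsbool import (
    attractors_async,
    influence_graph,
    inputs_of,
    parse_bnet,
    parse_sbml_qual,
    rename_nodes,
    sanitize_name,
    serialize_bnet,
)
from raflsbool.errors import (
    DuplicateTargetError,
    ModelSyntaxError,
    NameCollisionError,
    UndeclaredVariableError,
    UnsupportedModelError,
)
from raflsbool.expressions import And, Not, Or, Var
from raflsbool.fixtures import random_network

MINIMAL = "targets, factors\nA, A\nB, !A\n"

SBML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1"
      xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1" qual:required="true">
 <model id="m">
  <qual:listOfQualitativeSpecies>
   <qual:qualitativeSpecies qual:id="A" qual:maxLevel="{a_level}" qual:constant="false"/>
   <qual:qualitativeSpecies qual:id="B" qual:maxLevel="1" qual:constant="false"/>
  </qual:listOfQualitativeSpecies>
  <qual:listOfTransitions>
   <qual:transition qual:id="tr_B">
    <qual:listOfInputs>
     <qual:input qual:qualitativeSpecies="A" qual:transitionEffect="none"/>
    </qual:listOfInputs>
    <qual:listOfOutputs>
     <qual:output qual:qualitativeSpecies="B" qual:transitionEffect="assignmentLevel"/>
    </qual:listOfOutputs>
    <qual:listOfFunctionTerms>
     <qual:functionTerm qual:resultLevel="1">
      <math xmlns="http://www.w3.org/1998/Math/MathML">{math}</math>
     </qual:functionTerm>
     <qual:defaultTerm qual:resultLevel="0"/>
    </qual:listOfFunctionTerms>
   </qual:transition>
  </qual:listOfTransitions>
 </model>
</sbml>"""

NOT_A = "<apply><not/><apply><eq/><ci>A</ci><cn type=\"integer\">1</cn></apply></apply>"


class TestBnet:
    def test_minimal_two_node_model(self):
        net = parse_bnet(MINIMAL)
        assert net.nodes == ["A", "B"]
        assert net.rules["A"] == Var("A")
        assert net.rules["B"] == Not(Var("A"))

    def test_printed_apoptosis_rule_structure(self):
        net = parse_bnet(
            "targets, factors\n"
            "CAV1_rna, CAV1_rna\nCASP3_phosphorylated, CASP3_phosphorylated\n"
            "CASP8, CASP8\nTNFRSF10A_rna, TNFRSF10A_rna\nTNFRSF10B_rna, TNFRSF10B_rna\n"
            "Apoptosis_phenotype, !CAV1_rna & "
            "(CASP3_phosphorylated | CASP8 | TNFRSF10A_rna | TNFRSF10B_rna)\n"
        )
        rule = net.rules["Apoptosis_phenotype"]
        assert rule == And(
            (
                Not(Var("CAV1_rna")),
                Or(
                    (
                        Var("CASP3_phosphorylated"),
                        Var("CASP8"),
                        Var("TNFRSF10A_rna"),
                        Var("TNFRSF10B_rna"),
                    )
                ),
            )
        )
        assert net.phenotypes == ("Apoptosis_phenotype",)

    @pytest.mark.parametrize(
        "text,exc",
        [
            ("targets, factors\nA, B\n", UndeclaredVariableError),
            ("targets, factors\nA, A\nA, !A\n", DuplicateTargetError),
            ("targets, factors\nA, A &\n", ModelSyntaxError),
            ("A, A\n", ModelSyntaxError),  # missing header
        ],
    )
    def test_errors(self, text, exc):
        with pytest.raises(exc):
            parse_bnet(text)

    def test_syntax_error_carries_line_number(self):
        with pytest.raises(ModelSyntaxError) as err:
            parse_bnet("targets, factors\nA, A\nB, ((A)\n")
        assert err.value.line == 3

    def test_constant_rule_dialect(self):
        net = parse_bnet("targets, factors\nA, 1\n")
        assert serialize_bnet(net) == "targets, factors\nA, 1\n"

    @pytest.mark.parametrize("seed", range(100))
    def test_round_trip_random_networks(self, seed):
        net = random_network(n_nodes=3 + seed % 10, n_inputs=seed % 3, max_indegree=3, seed=seed)
        assert parse_bnet(serialize_bnet(net)) == net

    def test_round_trip_fixture(self, rafls):
        assert parse_bnet(serialize_bnet(rafls)) == rafls


class TestSbmlQual:
    def test_dialect_equivalence_with_bnet(self):
        net = parse_sbml_qual(SBML_TEMPLATE.format(a_level=1, math=NOT_A))
        assert net == parse_bnet(MINIMAL)

    def test_untargeted_species_become_self_rule_inputs(self):
        net = parse_sbml_qual(SBML_TEMPLATE.format(a_level=1, math=NOT_A))
        assert inputs_of(net) == {"A"}

    def test_multivalued_species_rejected(self):
        with pytest.raises(UnsupportedModelError, match="'A'"):
            parse_sbml_qual(SBML_TEMPLATE.format(a_level=2, math=NOT_A))

    def test_unsupported_math_rejected_with_transition_id(self):
        bad = "<apply><plus/><ci>A</ci><cn>1</cn></apply>"
        with pytest.raises(UnsupportedModelError, match="tr_B"):
            parse_sbml_qual(SBML_TEMPLATE.format(a_level=1, math=bad))

    def test_bare_ci_and_and_operator(self):
        math = "<apply><and/><ci>A</ci><ci>B</ci></apply>"
        net = parse_sbml_qual(SBML_TEMPLATE.format(a_level=1, math=math))
        assert net.rules["B"] == And((Var("A"), Var("B")))


class TestStructure:
    def test_inputs_of_conventions(self):
        net = parse_bnet("targets, factors\nA, 1\nB, A\nC, !C\n")
        assert inputs_of(net) == {"A"}  # constant is an input; !C self-loop is not

    def test_fixture_inputs(self, rafls):
        assert len(inputs_of(rafls)) == 17

    def test_influence_graph_edges(self):
        net = parse_bnet("targets, factors\nA, A\nB, !A\n")
        g = influence_graph(net)
        assert set(g.edges) == {("A", "A"), ("A", "B")}

    def test_apoptosis_in_edges(self, rafls):
        g = influence_graph(rafls)
        assert g.in_degree("Apoptosis_phenotype") == 5

    def test_sanitize_complex_species_name(self):
        assert sanitize_name("IKBA/NFKB/RELA") == "IKBA_NFKB_RELA"

    def test_rename_rewrites_rules(self):
        net = parse_bnet("targets, factors\nsa1, sa1\nB, sa1\n")
        out = rename_nodes(net, {"sa1": "TNF"})
        assert serialize_bnet(out) == "targets, factors\nTNF, TNF\nB, TNF\n"
        assert rename_nodes(net, {}) == net

    def test_rename_collision(self):
        net = parse_bnet("targets, factors\nA, A\nB, A\n")
        with pytest.raises(NameCollisionError):
            rename_nodes(net, {"A": "X", "B": "X"})

    @pytest.mark.parametrize("seed", range(20))
    def test_rename_preserves_attractors_up_to_relabelling(self, seed):
        net = random_network(n_nodes=2 + seed % 6, n_inputs=seed % 2, max_indegree=2, seed=seed)
        mapping = {n: f"R_{n}" for n in net.nodes}
        renamed = rename_nodes(net, mapping)
        orig = [
            sorted(tuple(sorted(s.items())) for s in att.states)
            for att in attractors_async(net)
        ]
        ren = [
            sorted(
                tuple(sorted((k[2:], v) for k, v in s.items())) for s in att.states
            )
            for att in attractors_async(renamed)
        ]
        assert sorted(map(tuple, orig)) == sorted(map(tuple, ren))
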