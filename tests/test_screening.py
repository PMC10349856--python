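"""Scenario scoring, module extraction, knockout matrices, drug screens."""

import warnings
from functools import reduce

import pytest

from raflsbool import (
    DrugSpec,
    Scenario,
    cell_specificity,
    combination_search,
    direct_regulators,
    drug_screen,
    extract_phenotype_module,
    knockout_matrix,
    run_scenario,
)
from raflsbool.errors import UndeclaredVariableError
from raflsbool.screening import score

APOPTOSIS = "Apoptosis_phenotype"
INFLAMMATION = "Inflammation_phenotype"
BONE = "Bone_Erosion_phenotype"
MATRIX = "Matrix_Degradation_phenotype"
PROLIF = "Cell_Growth_Survival_Proliferation_phenotype"

INFLAMED = dict(inputs={"MIR192": 0}, default_inputs=1)


def baseline():
    return Scenario("inflamed_baseline", **INFLAMED)


class TestScoreSemantics:
    def test_exhaustive_grid(self):
        # Fig-3-style codes: 1 match, 0 conflict, -1 if either side undefined
        for expected in (-1, 0, 1):
            for obtained in (-1, 0, 1):
                got = score(expected, obtained)
                if -1 in (expected, obtained):
                    assert got == -1
                elif expected == obtained:
                    assert got == 1
                else:
                    assert got == 0


class TestModules:
    def test_backward_closure_chain(self):
        from raflsbool import parse_bnet

        net = parse_bnet("targets, factors\nA, A\nB, A\nC, B\n")
        assert extract_phenotype_module(net, "C").nodes == ["A", "B", "C"]

    def test_apoptosis_module_contents(self, rafls):
        mod = extract_phenotype_module(rafls, APOPTOSIS)
        for required in ("CAV1_rna", "MIR192", "CASP3_phosphorylated", "CASP8",
                         "CASP9", "BAX", "TP53", "MDM2"):
            assert required in mod.nodes
        assert "WNT1" not in mod.nodes
        assert "SFRP5" not in mod.nodes

    def test_idempotent_and_monotone(self, rafls):
        mod = extract_phenotype_module(rafls, APOPTOSIS)
        again = extract_phenotype_module(mod, APOPTOSIS)
        assert again == mod

    def test_five_modules_share_a_core(self, rafls):
        cores = [
            set(extract_phenotype_module(rafls, p).nodes) for p in rafls.phenotypes
        ]
        shared = reduce(set.intersection, cores)
        assert shared == {"TNF"}

    def test_direct_regulators(self, rafls):
        assert set(direct_regulators(rafls, APOPTOSIS)) == {
            "CAV1_rna", "CASP3_phosphorylated", "CASP8",
            "TNFRSF10A_rna", "TNFRSF10B_rna",
        }
        assert set(direct_regulators(rafls, BONE)) == {"CTNNB1", "NFATC1", "AP1"}

    def test_no_regulators_for_constant_rule(self):
        from raflsbool import parse_bnet

        net = parse_bnet("targets, factors\nP, 1\n")
        assert direct_regulators(net, "P") == []


class TestScenarios:
    def test_il6_scenario_matches(self, rafls):
        sc = Scenario("IL6_ON", inputs={"IL6_Extracellular_space": 1},
                      expected={INFLAMMATION: 1})
        res = run_scenario(rafls, sc)
        assert res.obtained[INFLAMMATION] == 1
        assert res.scores[INFLAMMATION] == 1

    def test_tnf_alone_conflict_resolved_by_nfkb(self, rafls):
        sc = Scenario("TNF_alone", inputs={"TNF": 1}, expected={INFLAMMATION: 1})
        assert run_scenario(rafls, sc).scores[INFLAMMATION] == 0
        sc = Scenario("TNF_NFKB", inputs={"TNF": 1, "IKBA_NFKB_RELA": 1},
                      expected={INFLAMMATION: 1})
        assert run_scenario(rafls, sc).scores[INFLAMMATION] == 1

    def test_undefined_expectation_scores_undefined(self, rafls):
        sc = Scenario("undef", inputs={"TNF": 1}, expected={INFLAMMATION: -1})
        assert run_scenario(rafls, sc).scores[INFLAMMATION] == -1

    def test_unfixed_phenotype_reports_undefined(self, p53_mdm2):
        from raflsbool import BooleanNetwork

        net = BooleanNetwork(p53_mdm2.nodes, p53_mdm2.rules, ("TP53",))
        sc = Scenario("free", expected={"TP53": 1})
        res = run_scenario(net, sc)
        assert res.obtained["TP53"] == -1
        assert res.scores["TP53"] == -1


class TestScreens:
    def test_mmp3_knockout_controls_matrix_degradation(self, rafls):
        table = knockout_matrix(
            rafls, ["MMP3"], default_inputs=1, inputs={"MIR192": 0}
        ).table
        assert table.loc["MMP3_KO", MATRIX] == 0

    def test_cav1_knockout_enables_apoptosis(self, rafls):
        table = knockout_matrix(
            rafls, ["CAV1_rna"], default_inputs=1, inputs={"MIR192": 0}
        ).table
        assert table.loc["CAV1_rna_KO", APOPTOSIS] == 1

    def test_empty_candidate_list(self, rafls):
        assert len(knockout_matrix(rafls, [], default_inputs=1).table) == 0

    def test_unknown_candidate(self, rafls):
        with pytest.raises(UndeclaredVariableError):
            knockout_matrix(rafls, ["NOPE"], default_inputs=1)

    def test_il6_axis_blockade_silences_only_inflammation(self, rafls):
        res = drug_screen(rafls, [DrugSpec("Sarilumab", {"IL6R_sig": 0})], baseline())
        row = res.table.loc["Sarilumab"]
        assert row[INFLAMMATION] == 0
        assert row[APOPTOSIS] == 0
        assert row[BONE] == 1 and row[MATRIX] == 1 and row[PROLIF] == 1

    def test_anti_tnf_fails_to_suppress_inflammation(self, rafls):
        res = drug_screen(rafls, [DrugSpec("Etanercept", {"TNF": 0})], baseline())
        assert res.table.loc["Etanercept", INFLAMMATION] == 1

    def test_il7_plus_ap1_blockade_stops_bone_erosion(self, rafls):
        combo = DrugSpec("GSK2618960+T-5224", {"IL7": 0, "FOS": 0, "JUN": 0})
        res = drug_screen(rafls, [combo], baseline())
        assert res.table.loc["GSK2618960+T-5224", BONE] == 0

    def test_creb1_blockade_stops_proliferation(self, rafls):
        res = drug_screen(rafls, [DrugSpec("666-15", {"CREB1": 0})], baseline())
        assert res.table.loc["666-15", PROLIF] == 0

    def test_empty_drug_row_equals_baseline(self, rafls):
        res = drug_screen(rafls, [DrugSpec("placebo", {})], baseline())
        base = run_scenario(rafls, baseline()).obtained
        assert dict(res.table.loc["placebo"]) == base

    def test_absent_targets_skipped_with_warning(self, rafls):
        drug = DrugSpec("Anakinra", {"IL1B": 0})
        with pytest.warns(UserWarning, match="IL1B"):
            res = drug_screen(rafls, [drug], baseline())
        assert res.skipped == {"Anakinra": ["IL1B"]}
        # with no in-model target the row equals the baseline
        base = run_scenario(rafls, baseline()).obtained
        assert dict(res.table.loc["Anakinra"]) == base


class TestCombinationSearch:
    OBJECTIVE = {APOPTOSIS: 1, INFLAMMATION: 0, BONE: 0, MATRIX: 0, PROLIF: 0}
    CANDIDATES = ["CAV1_rna", "IL6R_sig", "IL7", "FOS", "JUN", "MMP3", "CREB1"]

    def test_recovers_minimal_subset_of_therapy_set(self, rafls):
        sols = combination_search(rafls, self.CANDIDATES, self.OBJECTIVE, 7, baseline())
        assert sols
        full = set(self.CANDIDATES)
        assert all(set(s) < full or set(s) == full for s in sols)
        assert min(len(s) for s in sols) == 6  # one of FOS/JUN suffices for AP-1

    def test_solutions_are_minimal(self, rafls):
        sols = combination_search(rafls, self.CANDIDATES, self.OBJECTIVE, 7, baseline())
        for sol in sols:
            for drop in sol:
                reduced = tuple(c for c in sol if c != drop)
                sc = Scenario(
                    "check", inputs={"MIR192": 0}, default_inputs=1,
                    mutations={c: 0 for c in reduced},
                )
                obtained = run_scenario(rafls, sc).obtained
                assert any(
                    obtained[ph] != v for ph, v in self.OBJECTIVE.items()
                ), f"{sol} minus {drop} still satisfies the objective"

    def test_satisfied_objective_returns_empty_clamp_set(self, rafls):
        sols = combination_search(
            rafls, ["CAV1_rna"], {INFLAMMATION: 1}, 1, baseline()
        )
        assert sols[0] == ()

    def test_max_size_zero_with_unsatisfied_objective(self, rafls):
        assert combination_search(rafls, ["CAV1_rna"], {APOPTOSIS: 1}, 0, baseline()) == []


class TestCellSpecificity:
    def test_counts_and_unmatched(self):
        counts = cell_specificity(["A", "B"], {"A": "FLS"})
        assert counts == {"FLS": 1, "unmatched": 1}

    def test_empty_node_list(self):
        assert cell_specificity([], {"A": "FLS"}) == {}

    def test_normalised_matching(self):
        counts = cell_specificity(["IKBA_NFKB_RELA"], {"IKBA/NFKB/RELA": "FLS"})
        assert counts == {"FLS": 1}
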