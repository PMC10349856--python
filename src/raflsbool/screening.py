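"""Scenario validation, phenotype-module extraction and in-silico drug
screening.

The pipeline for every condition is the same: clamp mutated nodes, assign
the listed inputs (remaining inputs take the scenario's default value),
propagate values, identify terminal trap spaces, and read each phenotype
off the trap spaces — 0/1 when all terminal trap spaces agree on a fixed
value, -1 (undefined) when the phenotype is unfixed or the trap spaces
disagree. Scenario scores compare expected against obtained values:

===== ========================================
score meaning
===== ========================================
1     both defined and equal (match)
0     both defined and different (conflict)
-1    expected or obtained undefined
===== ========================================

Drugs are clamp sets (inhibitors clamp their targets to 0, activators to
1); combinations are unions of clamp sets. Drug targets absent from the
model are recorded and skipped with a warning rather than failing the
screen.
"""

from __future__ import annotations

import itertools
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .errors import UndeclaredVariableError
from .expressions import support
from .network import BooleanNetwork, influence_graph, inputs_of, mutate, sanitize_name
from .trapspaces import terminal_trap_spaces

__all__ = [
    "Scenario",
    "ScenarioResult",
    "ScreenTable",
    "DrugSpec",
    "extract_phenotype_module",
    "direct_regulators",
    "run_scenario",
    "knockout_matrix",
    "drug_screen",
    "combination_search",
    "cell_specificity",
    "load_overlay",
    "load_drugs",
    "load_scenarios",
    "save_scenarios",
    "score",
]


@dataclass
class Scenario:
    """One validation condition: input assignments, mutations, expectations.

    ``default_inputs`` is the value given to every input the scenario does
    not list (0 = quiescent baseline, 1 = fully inflamed). ``expected`` maps
    phenotypes to 0/1/-1 (-1 = no defined expectation). ``variant`` records
    which model version ("modified"/"unmodified") the expectation refers to;
    ``known_conflict`` flags expectations that the model is known to miss
    without an additional model condition, with ``resolved_by`` naming the
    scenario that adds it.
    """

    name: str
    inputs: Dict[str, int] = field(default_factory=dict)
    mutations: Dict[str, int] = field(default_factory=dict)
    default_inputs: int = 0
    expected: Dict[str, int] = field(default_factory=dict)
    citation: str = ""
    variant: str = "modified"
    known_conflict: bool = False
    resolved_by: Optional[str] = None


@dataclass
class ScenarioResult:
    obtained: Dict[str, int]  # phenotype -> 0/1/-1
    scores: Dict[str, int]  # phenotype -> 1/0/-1
    fixed: Dict[str, int]  # full propagation result, for inspection
    n_trap_spaces: int


def score(expected: int, obtained: int) -> int:
    """Expected-vs-obtained comparison code (1 match / 0 conflict / -1 undefined)."""
    if expected == -1 or obtained == -1:
        return -1
    return 1 if expected == obtained else 0


@dataclass
class ScreenTable:
    """Perturbation x phenotype outcome matrix with cells in {-1, 0, 1}."""

    table: pd.DataFrame
    skipped: Dict[str, List[str]] = field(default_factory=dict)  # row -> absent targets


@dataclass
class DrugSpec:
    """A named drug as a clamp set: target node -> 0 (inhibit) / 1 (activate)."""

    name: str
    targets: Dict[str, int]


def extract_phenotype_module(net: BooleanNetwork, phenotype: str) -> BooleanNetwork:
    """The phenotype plus all its ancestors in the influence graph, with rules
    restricted to that node set (backward closure, so the result is a valid
    standalone network). Idempotent and monotone."""
    if phenotype not in net.rules:
        raise UndeclaredVariableError(f"unknown phenotype {phenotype!r}")
    g = influence_graph(net)
    keep = nx.ancestors(g, phenotype) | {phenotype}
    nodes = [n for n in net.nodes if n in keep]
    return BooleanNetwork(
        nodes,
        {n: net.rules[n] for n in nodes},
        tuple(p for p in net.phenotypes if p in keep),
    )


def direct_regulators(net: BooleanNetwork, phenotype: str) -> List[str]:
    """First-level upstream regulators: the variables of the phenotype's rule,
    in declaration order."""
    if phenotype not in net.rules:
        raise UndeclaredVariableError(f"unknown node {phenotype!r}")
    sup = support(net.rules[phenotype])
    return [n for n in net.nodes if n in sup]


def run_scenario(
    net: BooleanNetwork, sc: Scenario, free_limit: int = 20
) -> ScenarioResult:
    """Clamp mutations, assign inputs (+defaults), propagate, identify terminal
    trap spaces and score the phenotypes."""
    working = net
    for node, value in sc.mutations.items():
        working = mutate(working, node, value)
    seed = dict(sc.inputs)
    for node in inputs_of(working):
        if node not in seed and node not in sc.mutations:
            seed.setdefault(node, sc.default_inputs)
    unknown = set(seed) - set(working.rules)
    if unknown:
        raise UndeclaredVariableError(f"scenario assigns unknown nodes: {sorted(unknown)}")

    traps = terminal_trap_spaces_with_seed(working, seed, free_limit)
    obtained = {}
    for ph in net.phenotypes:
        values = {t[ph] for t in traps}
        obtained[ph] = values.pop() if len(values) == 1 else -1
    scores = {ph: score(sc.expected.get(ph, -1), obtained[ph]) for ph in net.phenotypes}
    fixed = {v: b for v, b in traps[0].items() if all(t[v] == b for t in traps)}
    return ScenarioResult(obtained, scores, fixed, len(traps))


def terminal_trap_spaces_with_seed(
    net: BooleanNetwork, seed: Mapping[str, int], free_limit: int = 20
):
    """Terminal trap spaces of ``net`` with ``seed`` nodes clamped."""
    working = net
    for node, value in seed.items():
        working = mutate(working, node, value)
    return terminal_trap_spaces(working, free_limit=free_limit)


def knockout_matrix(
    net: BooleanNetwork,
    candidates: Sequence[str],
    default_inputs: int,
    inputs: Optional[Mapping[str, int]] = None,
) -> ScreenTable:
    """One row per single knockout (clamp to 0) of each candidate.

    ``inputs`` optionally overrides individual input values on top of the
    global default (e.g. MIR192=0 under an otherwise all-active baseline).
    """
    rows = {}
    for cand in candidates:
        if cand not in net.rules:
            raise UndeclaredVariableError(f"unknown candidate {cand!r}")
        sc = Scenario(
            name=f"{cand}_KO",
            inputs=dict(inputs or {}),
            mutations={cand: 0},
            default_inputs=default_inputs,
        )
        rows[f"{cand}_KO"] = run_scenario(net, sc).obtained
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(net.phenotypes))
    if not len(table):
        table = pd.DataFrame(columns=list(net.phenotypes))
    return ScreenTable(table)


def drug_screen(
    net: BooleanNetwork, drugs: Sequence[DrugSpec], baseline: Scenario
) -> ScreenTable:
    """One row per drug: clamp all its in-model targets on top of the baseline
    scenario, then run the trap-space pipeline. Absent targets are skipped
    with a warning and recorded in ``skipped``."""
    rows = {}
    skipped: Dict[str, List[str]] = {}
    for drug in drugs:
        present = {t: v for t, v in drug.targets.items() if t in net.rules}
        absent = sorted(set(drug.targets) - set(present))
        if absent:
            skipped[drug.name] = absent
            warnings.warn(
                f"drug {drug.name!r}: target(s) {absent} absent from the model, skipped"
            )
        sc = Scenario(
            name=drug.name,
            inputs=dict(baseline.inputs),
            mutations={**baseline.mutations, **present},
            default_inputs=baseline.default_inputs,
        )
        rows[drug.name] = run_scenario(net, sc).obtained
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(net.phenotypes))
    if not len(table):
        table = pd.DataFrame(columns=list(net.phenotypes))
    return ScreenTable(table, skipped)


def combination_search(
    net: BooleanNetwork,
    candidates: Sequence[str],
    objective: Mapping[str, int],
    max_size: int,
    baseline: Scenario,
) -> List[Tuple[str, ...]]:
    """Breadth-first search for inclusion-minimal knockout sets achieving
    ``objective`` (phenotype -> required value) on top of ``baseline``.

    Subsets are explored by increasing size, in the (deterministic) order of
    the candidate list; supersets of found solutions are pruned. Candidates
    are clamped to 0 (knock-outs), the in-silico analogue of inhibition.
    """
    for ph in objective:
        if ph not in net.rules:
            raise UndeclaredVariableError(f"unknown phenotype {ph!r}")
    for cand in candidates:
        if cand not in net.rules:
            raise UndeclaredVariableError(f"unknown candidate {cand!r}")

    solutions: List[Tuple[str, ...]] = []
    for size in range(0, max_size + 1):
        for combo in itertools.combinations(candidates, size):
            if any(set(sol) <= set(combo) for sol in solutions):
                continue  # superset of a known minimal solution
            sc = Scenario(
                name="+".join(combo) or "baseline",
                inputs=dict(baseline.inputs),
                mutations={**baseline.mutations, **{c: 0 for c in combo}},
                default_inputs=baseline.default_inputs,
            )
            obtained = run_scenario(net, sc).obtained
            if all(obtained.get(ph) == v for ph, v in objective.items()):
                solutions.append(combo)
    return solutions


def cell_specificity(
    nodes: Iterable[str], overlay: Mapping[str, str]
) -> Counter:
    """Count nodes per cell type using a name -> cell-type overlay.

    Matching is on sanitised, case-folded names; nodes without an overlay
    entry are tallied under ``"unmatched"``.
    """
    norm = {sanitize_name(k).casefold(): v for k, v in overlay.items()}
    counts: Counter = Counter()
    for node in nodes:
        key = sanitize_name(node).casefold()
        counts[norm.get(key, "unmatched")] += 1
    return counts


def load_overlay(path) -> Dict[str, str]:
    """Two-column TSV (component, cell type) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"overlay file {path} must have two tab-separated columns")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def load_drugs(path) -> List[DrugSpec]:
    """TSV with columns drug, target, clamp -> list of DrugSpec (grouped)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"clamp": int})
    required = {"drug", "target", "clamp"}
    if not required <= set(df.columns):
        raise ValueError(f"drug table needs columns {sorted(required)}")
    drugs: List[DrugSpec] = []
    for name, group in df.groupby("drug", sort=False):
        drugs.append(DrugSpec(str(name), dict(zip(group["target"], group["clamp"]))))
    return drugs


def load_scenarios(path) -> List[Scenario]:
    with open(path) as fh:
        raw = json.load(fh)
    return [Scenario(**entry) for entry in raw]


def save_scenarios(scenarios: Sequence[Scenario], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(sc) for sc in scenarios], fh, indent=2)
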