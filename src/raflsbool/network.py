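"""The Boolean network container and structural operations.

A :class:`BooleanNetwork` is an ordered set of named nodes, one Boolean rule
per node, and a subset of nodes flagged as phenotype (sink/readout) nodes.
Input nodes follow the CaSQ idiom: a node is an input iff its rule is exactly
the self-variable or a constant, so that the value of an input is an
experimental condition rather than a regulated quantity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Set

import networkx as nx

from .errors import (
    DuplicateTargetError,
    NameCollisionError,
    UndeclaredVariableError,
)
from .expressions import (
    Const,
    RuleExpression,
    Var,
    substitute,
    support,
)

__all__ = [
    "NAME_PATTERN",
    "sanitize_name",
    "BooleanNetwork",
    "State",
    "Subspace",
    "inputs_of",
    "influence_graph",
    "rename_nodes",
    "mutate",
]

NAME_PATTERN = re.compile(r"^[A-Za-z0-9_]+$")

#: Total assignment node -> {0, 1}.
State = Dict[str, int]

#: Partial assignment node -> {0, 1, -1}; -1 marks a free (unfixed) node.
Subspace = Dict[str, int]

FREE = -1


def sanitize_name(name: str) -> str:
    """Normalise a species name to the ``[A-Za-z0-9_]+`` charset.

    Complex-species names such as ``IKBA/NFKB/RELA`` become
    ``IKBA_NFKB_RELA``; runs of invalid characters collapse to one underscore.
    """
    out = re.sub(r"[^A-Za-z0-9_]+", "_", name).strip("_")
    if not out:
        raise ValueError(f"name {name!r} sanitises to an empty string")
    return out


@dataclass
class BooleanNetwork:
    """Named Boolean variables with one rule each.

    Parameters
    ----------
    nodes : ordered node names, unique, matching ``[A-Za-z0-9_]+``.
    rules : total mapping node -> :class:`RuleExpression`; every variable a
        rule mentions must itself be a declared node.
    phenotypes : subset of nodes flagged as phenotype outputs.
    """

    nodes: list
    rules: Dict[str, RuleExpression]
    phenotypes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.nodes = list(self.nodes)
        self.phenotypes = tuple(self.phenotypes)
        seen = set()
        for n in self.nodes:
            if not NAME_PATTERN.match(n):
                raise ValueError(f"invalid node name {n!r}")
            if n in seen:
                raise DuplicateTargetError(f"duplicate node {n!r}")
            seen.add(n)
        missing = seen.symmetric_difference(self.rules)
        if missing:
            raise UndeclaredVariableError(
                f"rules mapping is not total over nodes: {sorted(missing)}"
            )
        for n, rule in self.rules.items():
            undeclared = support(rule) - seen
            if undeclared:
                raise UndeclaredVariableError(
                    f"rule of {n!r} references undeclared node(s) {sorted(undeclared)}"
                )
        bad = set(self.phenotypes) - seen
        if bad:
            raise UndeclaredVariableError(f"phenotypes not in nodes: {sorted(bad)}")

    def copy(self) -> "BooleanNetwork":
        return BooleanNetwork(list(self.nodes), dict(self.rules), self.phenotypes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.rules == other.rules
            and self.phenotypes == other.phenotypes
        )


def inputs_of(net: BooleanNetwork) -> Set[str]:
    """Nodes whose rule is the self-variable or a constant.

    These are the experimental-condition nodes; a negative self-loop such as
    ``A, !A`` is regulation, not an input.
    """
    out = set()
    for n in net.nodes:
        rule = net.rules[n]
        if isinstance(rule, Const) or (isinstance(rule, Var) and rule.name == n):
            out.add(n)
    return out


def influence_graph(net: BooleanNetwork) -> nx.DiGraph:
    """Directed regulator -> target graph: edge (u, v) iff u occurs in v's rule."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for target in net.nodes:
        for reg in support(net.rules[target]):
            g.add_edge(reg, target)
    return g


def rename_nodes(net: BooleanNetwork, mapping: Mapping[str, str]) -> BooleanNetwork:
    """Rename nodes consistently through rules; dynamics are isomorphic.

    ``mapping`` entries absent from the network are ignored; a mapping that
    merges two names raises :class:`NameCollisionError`.
    """

    def tr(name: str) -> str:
        return mapping.get(name, name)

    new_names = [tr(n) for n in net.nodes]
    if len(set(new_names)) != len(new_names):
        raise NameCollisionError("renaming maps two nodes to the same name")

    def rewrite(expr: RuleExpression) -> RuleExpression:
        if isinstance(expr, Var):
            return Var(tr(expr.name))
        if isinstance(expr, Const):
            return expr
        if hasattr(expr, "child"):
            return type(expr)(rewrite(expr.child))
        return type(expr)(tuple(rewrite(c) for c in expr.children))

    rules = {tr(n): rewrite(r) for n, r in net.rules.items()}
    return BooleanNetwork(new_names, rules, tuple(tr(p) for p in net.phenotypes))


def mutate(net: BooleanNetwork, node: str, value: int) -> BooleanNetwork:
    """Clamp ``node`` to ``value`` (knock-out 0 / knock-in 1).

    The node's rule is replaced by a constant, so no upstream regulation can
    change it; repeating the mutation with a different value simply overwrites
    the clamp (last one wins).
    """
    if node not in net.rules:
        raise UndeclaredVariableError(f"unknown node {node!r}")
    if value not in (0, 1):
        raise ValueError(f"clamp value must be 0 or 1, got {value!r}")
    out = net.copy()
    out.rules[node] = Const(bool(value))
    return out
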