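"""Value propagation: fixing components and reducing the model.

Given seed assignments (clamped inputs or mutated internal nodes), the seed
values are substituted into every downstream rule; any rule that thereby
becomes constant fixes its node, and the new constant is propagated in turn,
iterating to a fixpoint. The reduced model over the remaining free nodes
preserves all terminal trap spaces of the clamped original — the property
that makes the reduction sound for asymptotic analysis.

Seeding an internal node means clamping it: its own rule is discarded, as
for a knock-out/knock-in mutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple, Union

from .errors import ContradictorySeedError, UndeclaredVariableError
from .expressions import (
    Const,
    RuleExpression,
    evaluate,
    simplify,
    substitute,
    support,
)
from .network import BooleanNetwork

__all__ = ["PropagationResult", "propagate"]

# rules whose remaining support exceeds this are checked by folding only;
# supports in curated signalling models are far smaller
_EXHAUSTIVE_SUPPORT_LIMIT = 12


@dataclass
class PropagationResult:
    """Outcome of value propagation.

    ``fixed`` holds the seed assignments plus every inferred constant;
    ``reduced`` is the network over the remaining free nodes, with all fixed
    values substituted away. The two node sets partition the original nodes,
    and re-running propagation on ``reduced`` with an empty seed is the
    identity.
    """

    fixed: Dict[str, int]
    reduced: BooleanNetwork


def _normalise_seed(
    seed: Union[Mapping[str, int], Iterable[Tuple[str, int]], None],
) -> Dict[str, int]:
    if seed is None:
        return {}
    items = seed.items() if isinstance(seed, Mapping) else seed
    out: Dict[str, int] = {}
    for node, value in items:
        value = int(value)
        if value not in (0, 1):
            raise ValueError(f"seed value for {node!r} must be 0 or 1")
        if node in out and out[node] != value:
            raise ContradictorySeedError(
                f"node {node!r} seeded at both {out[node]} and {value}"
            )
        out[node] = value
    return out


def _rule_constant(rule: RuleExpression) -> int | None:
    """Return 0/1 if ``rule`` is constant, else None.

    Constant folding first; residual constancy (e.g. ``A | !A``) is detected
    by exhaustive evaluation over the rule's support when it is small enough.
    """
    rule = simplify(rule)
    if isinstance(rule, Const):
        return int(rule.value)
    names = sorted(support(rule))
    if len(names) > _EXHAUSTIVE_SUPPORT_LIMIT:
        return None
    first = None
    for values in itertools.product((0, 1), repeat=len(names)):
        v = evaluate(rule, dict(zip(names, values)))
        if first is None:
            first = v
        elif v != first:
            return None
    return first


def propagate(
    net: BooleanNetwork,
    seed: Union[Mapping[str, int], Iterable[Tuple[str, int]], None] = None,
) -> PropagationResult:
    """Propagate ``seed`` assignments through ``net`` to a fixpoint.

    Deterministic declaration-order worklist; the fixed set is confluent
    (independent of processing order) because every inferred constant is
    logically forced by the seed.
    """
    fixed = _normalise_seed(seed)
    unknown = set(fixed) - set(net.rules)
    if unknown:
        raise UndeclaredVariableError(f"seed names unknown nodes: {sorted(unknown)}")

    rules: Dict[str, RuleExpression] = {
        n: net.rules[n] for n in net.nodes if n not in fixed
    }
    changed = True
    while changed:
        changed = False
        for node in [n for n in net.nodes if n in rules]:
            rule = simplify(substitute(rules[node], fixed))
            # an input's self-rule (Var(node)) never becomes constant unless seeded
            value = _rule_constant(rule)
            if value is not None:
                fixed[node] = value
                del rules[node]
                changed = True
            else:
                rules[node] = rule

    remaining = [n for n in net.nodes if n in rules]
    reduced = BooleanNetwork(
        remaining,
        {n: rules[n] for n in remaining},
        tuple(p for p in net.phenotypes if p in rules),
    )
    return PropagationResult(fixed, reduced)
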