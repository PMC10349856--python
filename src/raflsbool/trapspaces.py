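"""Trap spaces: closure checking, terminal (minimal) trap space identification
and a brute-force oracle.

A trap space is a subspace the dynamics cannot leave: every fixed node's rule
evaluates to the fixed value under every completion of the free variables. A
terminal trap space contains no smaller trap space; terminal trap spaces
approximate the attractors and are the readout used for every scenario and
screen in this package (values -1/0/1 = unfixed/OFF/ON).
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence

from .dynamics import bottom_scc_spans
from .errors import CapacityError
from .expressions import Const, compile_expr, evaluate, simplify, substitute, support
from .network import BooleanNetwork, Subspace
from .reduction import propagate

__all__ = [
    "is_trap_space",
    "terminal_trap_spaces",
    "brute_force_terminal_trap_spaces",
    "subspace_contains",
]

_BRUTE_FORCE_LIMIT = 8


def is_trap_space(net: BooleanNetwork, s: Subspace) -> bool:
    """True iff ``s`` (total mapping node -> -1/0/1) is closed under the dynamics.

    Checked exhaustively over each fixed node's rule support, which is small
    in curated models.
    """
    fixed = {v: b for v, b in s.items() if b != -1}
    for v, b in fixed.items():
        rule = simplify(substitute(net.rules[v], fixed))
        if isinstance(rule, Const):
            if int(rule.value) != b:
                return False
            continue
        free_sup = sorted(support(rule))
        for values in itertools.product((0, 1), repeat=len(free_sup)):
            if evaluate(rule, dict(zip(free_sup, values))) != b:
                return False
    return True


def subspace_contains(outer: Subspace, inner: Subspace) -> bool:
    """True iff every state of ``inner`` lies in ``outer``."""
    return all(b == -1 or inner.get(v) == b for v, b in outer.items())


def _minimal(spaces: List[Subspace]) -> List[Subspace]:
    keep = []
    for s in spaces:
        if any(t != s and subspace_contains(s, t) for t in spaces):
            continue  # s strictly contains another trap space
        if s not in keep:
            keep.append(s)
    return keep


def _closure(net: BooleanNetwork, span: Subspace) -> Subspace:
    """Smallest trap space containing ``span``: free fixed nodes whose rules
    can deviate within the subspace, iterating to stability."""
    s = dict(span)
    changed = True
    while changed:
        changed = False
        fixed = {v: b for v, b in s.items() if b != -1}
        for v, b in list(fixed.items()):
            rule = simplify(substitute(net.rules[v], fixed))
            if isinstance(rule, Const):
                ok = int(rule.value) == b
            else:
                names = sorted(support(rule))
                ok = all(
                    evaluate(rule, dict(zip(names, vals))) == b
                    for vals in itertools.product((0, 1), repeat=len(names))
                )
            if not ok:
                s[v] = -1
                changed = True
                break  # fixed part changed; re-derive substitutions
    return s


def terminal_trap_spaces(net: BooleanNetwork, free_limit: int = 20) -> List[Subspace]:
    """Exactly the terminal (inclusion-minimal) trap spaces of ``net``.

    Constant rules are percolated first; the remaining free core must have at
    most ``free_limit`` nodes, otherwise a :class:`CapacityError` advises
    propagating fixed inputs first. On the core, every minimal trap space is
    the percolation-closure of the span of some asynchronous attractor, which
    is what this computes (validated against the 3^n brute-force oracle).
    """
    res = propagate(net)
    core = res.reduced
    if len(core.nodes) > free_limit:
        raise CapacityError(
            f"{len(core.nodes)} free nodes after constant propagation exceeds "
            f"free_limit={free_limit}; clamp inputs (propagate) first"
        )
    if not core.nodes:
        return [dict(res.fixed)]
    closures = _minimal([_closure(core, span) for span in bottom_scc_spans(core)])
    out = []
    for c in closures:
        full = dict(res.fixed)
        full.update(c)
        out.append({v: full[v] for v in net.nodes})
    return sorted(out, key=lambda s: tuple(s[v] for v in net.nodes))


def brute_force_terminal_trap_spaces(
    net: BooleanNetwork, max_nodes: int = _BRUTE_FORCE_LIMIT
) -> List[Subspace]:
    """Oracle: enumerate all 3^n subspaces, filter by :func:`is_trap_space`,
    keep the inclusion-minimal ones. Intended for testing on tiny models."""
    n = len(net.nodes)
    if n > max_nodes:
        raise CapacityError(f"brute force limited to {max_nodes} nodes, got {n}")
    index = {v: i for i, v in enumerate(net.nodes)}
    funcs = [compile_expr(net.rules[v], index) for v in net.nodes]
    supports = [sorted(index[u] for u in support(net.rules[v])) for v in net.nodes]

    def closed(vals) -> bool:
        state = [b if b != -1 else 0 for b in vals]
        for i, b in enumerate(vals):
            if b == -1:
                continue
            free = [j for j in supports[i] if vals[j] == -1]
            for combo in itertools.product((0, 1), repeat=len(free)):
                for j, x in zip(free, combo):
                    state[j] = x
                if funcs[i](state) != b:
                    for j in free:
                        state[j] = 0
                    return False
            for j in free:
                state[j] = 0
        return True

    traps = [
        dict(zip(net.nodes, vals))
        for vals in itertools.product((-1, 0, 1), repeat=n)
        if closed(vals)
    ]
    return sorted(
        _minimal(traps), key=lambda s: tuple(s[v] for v in net.nodes)
    )
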