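"""Asynchronous dynamics: explicit state-transition graphs, attractors,
random asynchronous walks and oscillation statistics.

Under the asynchronous update scheme, one unstable variable (a variable
whose rule value differs from its current value) changes per step. Exact
attractor identification builds the full state-transition graph and takes
its bottom strongly connected components; the random walk emulates the
uniform asynchronous simulation of interactive platforms, which is how the
oscillations of the TP53–MDM2 negative feedback loop are observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .errors import CapacityError
from .network import BooleanNetwork, State, Subspace
from .expressions import compile_expr, support

__all__ = [
    "Attractor",
    "AttractorReport",
    "attractors_async",
    "bottom_scc_spans",
    "random_async_trace",
    "NodeOscillation",
    "OscillationReport",
    "oscillation_report",
]

_STG_LIMIT = 18


def _compiled(net: BooleanNetwork):
    index = {n: i for i, n in enumerate(net.nodes)}
    return index, [compile_expr(net.rules[n], index) for n in net.nodes]


def _async_stg(net: BooleanNetwork) -> nx.DiGraph:
    """Explicit asynchronous STG; states are integer-encoded (node i = bit i)."""
    n = len(net.nodes)
    if n > _STG_LIMIT:
        raise CapacityError(
            f"{n} nodes exceeds the explicit-STG budget of {_STG_LIMIT}; "
            "propagate fixed inputs first"
        )
    _, funcs = _compiled(net)
    g = nx.DiGraph()
    for code in range(1 << n):
        state = [(code >> i) & 1 for i in range(n)]
        g.add_node(code)
        for i, f in enumerate(funcs):
            if f(state) != state[i]:
                g.add_edge(code, code ^ (1 << i))
    return g


def _decode(code: int, nodes: Sequence[str]) -> State:
    return {v: (code >> i) & 1 for i, v in enumerate(nodes)}


@dataclass
class Attractor:
    states: List[State]
    kind: str  # "fixed-point" | "cyclic"


AttractorReport = List[Attractor]


def _bottom_sccs(g: nx.DiGraph) -> List[List[int]]:
    cond = nx.condensation(g)
    return [
        sorted(cond.nodes[c]["members"])
        for c in cond.nodes
        if cond.out_degree(c) == 0
    ]


def attractors_async(net: BooleanNetwork) -> AttractorReport:
    """All asynchronous attractors (bottom SCCs of the explicit STG).

    A singleton bottom SCC has no outgoing transitions, hence no unstable
    variable: it is a fixed point. Capacity-limited to 18 nodes.
    """
    g = _async_stg(net)
    report = []
    for members in sorted(_bottom_sccs(g)):
        states = [_decode(c, net.nodes) for c in members]
        kind = "fixed-point" if len(states) == 1 else "cyclic"
        report.append(Attractor(states, kind))
    return report


def bottom_scc_spans(net: BooleanNetwork) -> List[Subspace]:
    """Smallest subspace spanning each attractor (node fixed iff constant
    across the attractor's states, -1 otherwise)."""
    spans = []
    for att in attractors_async(net):
        span: Subspace = {}
        for v in net.nodes:
            values = {s[v] for s in att.states}
            span[v] = values.pop() if len(values) == 1 else -1
        spans.append(span)
    return spans


def random_async_trace(
    net: BooleanNetwork, initial: State, steps: int, seed: int
) -> List[State]:
    """Uniform asynchronous random walk of ``steps`` updates from ``initial``.

    Each step flips one uniformly chosen unstable node; when no node is
    unstable the state repeats. Identical seed gives an identical trace.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    index, funcs = _compiled(net)
    targets = _downstream_indices(net, index)
    rng = np.random.default_rng(seed)

    state = [int(initial[v]) for v in net.nodes]
    unstable = {i for i, f in enumerate(funcs) if f(state) != state[i]}
    trace = [dict(zip(net.nodes, state))]
    for _ in range(steps):
        if unstable:
            i = sorted(unstable)[rng.integers(len(unstable))]
            state[i] ^= 1
            for j in targets[i]:
                if funcs[j](state) != state[j]:
                    unstable.add(j)
                else:
                    unstable.discard(j)
        trace.append(dict(zip(net.nodes, state)))
    return trace


def _downstream_indices(net: BooleanNetwork, index: Dict[str, int]):
    """For each node index, the indices whose rules mention it (incl. itself)."""
    targets = {i: {i} for i in range(len(net.nodes))}
    for tgt in net.nodes:
        for reg in support(net.rules[tgt]):
            targets[index[reg]].add(index[tgt])
    return {i: sorted(js) for i, js in targets.items()}


@dataclass
class NodeOscillation:
    toggles: int
    activity: float  # mean value over the analysed trace segment
    classification: str  # "oscillating" | "stably-ON" | "stably-OFF"


OscillationReport = Dict[str, NodeOscillation]


def oscillation_report(
    trace: Sequence[State],
    nodes: Sequence[str] | None = None,
    burn_in: int | None = None,
) -> OscillationReport:
    """Per-node toggle counts, activity fractions and classifications.

    Statistics are computed on the post-burn-in segment (default burn-in:
    10% of the trace). A node is *oscillating* when it toggles at least
    twice and its activity fraction lies strictly between 0 and 1; otherwise
    it is classed stably-ON/OFF by its final value in the segment.
    """
    if not trace:
        raise ValueError("empty trace")
    if burn_in is None:
        burn_in = len(trace) // 10
    if burn_in >= len(trace):
        raise ValueError("burn_in leaves an empty trace segment")
    segment = trace[burn_in:]
    if nodes is None:
        nodes = list(segment[0])
    report: OscillationReport = {}
    for v in nodes:
        values = [s[v] for s in segment]
        toggles = sum(a != b for a, b in zip(values, values[1:]))
        activity = float(np.mean(values))
        if toggles >= 2 and 0.0 < activity < 1.0:
            cls = "oscillating"
        else:
            cls = "stably-ON" if values[-1] == 1 else "stably-OFF"
        report[v] = NodeOscillation(toggles, activity, cls)
    return report
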