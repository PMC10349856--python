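"""Continuous-time Boolean stochastic simulation (kinetic Monte Carlo).

Each Boolean variable flips asynchronously as a continuous-time Markov jump
process: in a state, the eligible events are the flips of non-clamped nodes
whose rule value differs from their current value; node ``v`` flips up with
propensity ``rate_up[v]`` and down with ``rate_down[v]``. Waiting times are
exponential in the propensity sum and the flip is chosen proportionally to
its propensity — the exact Gillespie algorithm on the asynchronous
transition graph. Averaging many trajectories yields time-dependent
activation probabilities per node, the continuous-time analogue of the trap
space readout: a phenotype fixed by propagation at b converges to
probability b, while oscillating motifs settle at intermediate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np

from .errors import UnboundVariableError, UndeclaredVariableError
from .expressions import compile_expr, support
from .network import BooleanNetwork, mutate  # re-export: mutation = clamping
from .dynamics import _downstream_indices

__all__ = [
    "RateSpec",
    "InitialCondition",
    "TrajectoryEnsemble",
    "mutate",
    "simulate_ct",
    "probability_at",
]

DEFAULT_MAX_TIME = 40.0
GRID_POINTS = 200


@dataclass
class RateSpec:
    """Per-node flip rates (per unit time); unnamed nodes default to 1.0."""

    rate_up: Mapping[str, float] = field(default_factory=dict)
    rate_down: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for rates in (self.rate_up, self.rate_down):
            for node, r in rates.items():
                if not r > 0:
                    raise ValueError(f"rate for {node!r} must be > 0, got {r}")

    def up(self, node: str) -> float:
        return float(self.rate_up.get(node, 1.0))

    def down(self, node: str) -> float:
        return float(self.rate_down.get(node, 1.0))


@dataclass
class InitialCondition:
    """Bernoulli start probabilities (default 0) plus clamped nodes.

    Clamped nodes start at, and are pinned to, their clamp value: they are
    excluded from flipping for the whole simulation. Model inputs (self-rule
    nodes) are inert under the dynamics anyway, so for inputs an initial
    probability of 0/1 and a clamp are equivalent.
    """

    probs: Mapping[str, float] = field(default_factory=dict)
    clamped: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for node, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"initial probability for {node!r} out of [0,1]: {p}")
        for node, v in self.clamped.items():
            if v not in (0, 1):
                raise ValueError(f"clamp value for {node!r} must be 0 or 1")


@dataclass
class TrajectoryEnsemble:
    """Monte-Carlo per-node activation-probability curves on a uniform grid."""

    times: np.ndarray
    nodes: list
    prob: np.ndarray  # shape (n_nodes, n_grid), values in [0, 1]
    n_traj: int
    seed: int

    def curve(self, node: str) -> np.ndarray:
        try:
            return self.prob[self.nodes.index(node)]
        except ValueError:
            raise UndeclaredVariableError(f"unknown node {node!r}") from None

    def stderr(self, node: str, t: float) -> float:
        p = probability_at(self, node, t)
        return float(np.sqrt(p * (1.0 - p) / self.n_traj))


def simulate_ct(
    net: BooleanNetwork,
    init: InitialCondition | None = None,
    rates: RateSpec | None = None,
    max_time: float = DEFAULT_MAX_TIME,
    n_traj: int = 5000,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Run ``n_traj`` Gillespie realisations up to ``max_time``.

    Returns probability curves on a uniform grid of 200 time points;
    identical seeds give identical ensembles.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if not max_time > 0:
        raise ValueError("max_time must be > 0")
    init = init or InitialCondition()
    rates = rates or RateSpec()
    for name in list(init.probs) + list(init.clamped):
        if name not in net.rules:
            raise UndeclaredVariableError(f"unknown node {name!r}")

    nodes = list(net.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    funcs = [compile_expr(net.rules[v], index) for v in nodes]
    targets = _downstream_indices(net, index)
    clamped = {index[v]: int(b) for v, b in init.clamped.items()}
    p0 = np.array([float(init.probs.get(v, 0.0)) for v in nodes])
    r_up = [rates.up(v) for v in nodes]
    r_down = [rates.down(v) for v in nodes]

    grid = np.linspace(0.0, max_time, GRID_POINTS)
    counts = np.zeros((n, GRID_POINTS))
    rng = np.random.default_rng(seed)

    for _ in range(n_traj):
        state = (rng.random(n) < p0).astype(int).tolist()
        for i, b in clamped.items():
            state[i] = b
        unstable = {
            i for i in range(n) if i not in clamped and funcs[i](state) != state[i]
        }
        t = 0.0
        gi = 0  # next grid point not yet recorded
        while gi < GRID_POINTS:
            if not unstable:  # absorbing state
                counts[:, gi:] += np.asarray(state)[:, None]
                break
            order = sorted(unstable)
            props = [r_up[i] if state[i] == 0 else r_down[i] for i in order]
            total = sum(props)
            t_next = t + rng.exponential(1.0 / total)
            gi_end = (
                GRID_POINTS
                if t_next > max_time
                else int(np.searchsorted(grid, t_next, side="left"))
            )
            if gi_end > gi:
                counts[:, gi:gi_end] += np.asarray(state)[:, None]
                gi = gi_end
            if gi >= GRID_POINTS:
                break
            u = rng.random() * total
            acc = 0.0
            for i, p in zip(order, props):
                acc += p
                if u < acc:
                    break
            state[i] ^= 1
            for j in targets[i]:
                if j in clamped:
                    continue
                if funcs[j](state) != state[j]:
                    unstable.add(j)
                else:
                    unstable.discard(j)
            t = t_next

    return TrajectoryEnsemble(grid, nodes, counts / n_traj, n_traj, seed)


def probability_at(ens: TrajectoryEnsemble, node: str, t: float) -> float:
    """Step-wise (last-observation) curve lookup at time ``t``."""
    if not 0.0 <= t <= ens.times[-1]:
        raise ValueError(f"t={t} outside [0, {ens.times[-1]}]")
    gi = int(np.searchsorted(ens.times, t, side="right") - 1)
    return float(ens.curve(node)[gi])
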