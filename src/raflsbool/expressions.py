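"""Boolean rule expressions.

A rule is a finite tree over constants, variables, negation, conjunction and
disjunction — exactly the operator set of BoolNet / SBML-qual Boolean models
(``!``, ``&``, ``|`` in text form). Expressions are immutable and hashable so
they can be compared structurally, used as dict keys and shared freely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, FrozenSet, Iterable, Mapping

from .errors import UnboundVariableError

__all__ = [
    "RuleExpression",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "evaluate",
    "support",
    "substitute",
    "simplify",
    "to_string",
    "compile_expr",
    "truth_table_equal",
]


class RuleExpression:
    """Abstract base for Boolean rule syntax trees."""

    __slots__ = ()


@dataclass(frozen=True)
class Const(RuleExpression):
    value: bool

    def __post_init__(self):
        object.__setattr__(self, "value", bool(self.value))


@dataclass(frozen=True)
class Var(RuleExpression):
    name: str


@dataclass(frozen=True)
class Not(RuleExpression):
    child: RuleExpression


@dataclass(frozen=True)
class And(RuleExpression):
    children: tuple

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise ValueError("And requires at least 2 children")


@dataclass(frozen=True)
class Or(RuleExpression):
    children: tuple

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise ValueError("Or requires at least 2 children")


def _nary(cls, children: Iterable[RuleExpression]) -> RuleExpression:
    """Build And/Or collapsing the degenerate 0/1-child cases."""
    children = list(children)
    if not children:
        return Const(cls is And)
    if len(children) == 1:
        return children[0]
    return cls(tuple(children))


def make_and(children: Iterable[RuleExpression]) -> RuleExpression:
    return _nary(And, children)


def make_or(children: Iterable[RuleExpression]) -> RuleExpression:
    return _nary(Or, children)


def evaluate(expr: RuleExpression, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under ``state`` (node -> 0/1) with standard semantics."""
    if isinstance(expr, Const):
        return int(expr.value)
    if isinstance(expr, Var):
        try:
            return int(state[expr.name])
        except KeyError:
            raise UnboundVariableError(expr.name) from None
    if isinstance(expr, Not):
        return 1 - evaluate(expr.child, state)
    if isinstance(expr, And):
        return int(all(evaluate(c, state) for c in expr.children))
    if isinstance(expr, Or):
        return int(any(evaluate(c, state) for c in expr.children))
    raise TypeError(f"not a RuleExpression: {expr!r}")


def support(expr: RuleExpression) -> FrozenSet[str]:
    """The set of variable names occurring in ``expr``."""
    if isinstance(expr, Const):
        return frozenset()
    if isinstance(expr, Var):
        return frozenset((expr.name,))
    if isinstance(expr, Not):
        return support(expr.child)
    return frozenset().union(*(support(c) for c in expr.children))


def substitute(expr: RuleExpression, assignment: Mapping[str, int]) -> RuleExpression:
    """Replace every variable present in ``assignment`` by the matching constant."""
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Var):
        if expr.name in assignment:
            return Const(bool(assignment[expr.name]))
        return expr
    if isinstance(expr, Not):
        return Not(substitute(expr.child, assignment))
    cls = type(expr)
    return cls(tuple(substitute(c, assignment) for c in expr.children))


def simplify(expr: RuleExpression) -> RuleExpression:
    """Constant-fold ``expr``.

    Applies identity/annihilator laws for constants only; the result contains
    no Const underneath an operator and is logically equivalent to the input.
    """
    if isinstance(expr, (Const, Var)):
        return expr
    if isinstance(expr, Not):
        c = simplify(expr.child)
        if isinstance(c, Const):
            return Const(not c.value)
        return Not(c)
    kept = []
    absorbing = isinstance(expr, Or)  # Const(True) absorbs Or, Const(False) absorbs And
    for child in expr.children:
        c = simplify(child)
        if isinstance(c, Const):
            if c.value == absorbing:
                return Const(absorbing)
            continue  # neutral element, drop
        kept.append(c)
    return _nary(type(expr), kept)


def to_string(expr: RuleExpression) -> str:
    """Render with ``!``/``&``/``|`` and minimal parentheses (``!`` > ``&`` > ``|``)."""

    def render(e: RuleExpression, parent_prec: int) -> str:
        if isinstance(e, Const):
            return "1" if e.value else "0"
        if isinstance(e, Var):
            return e.name
        if isinstance(e, Not):
            return "!" + render(e.child, 3)
        prec = 2 if isinstance(e, And) else 1
        sep = " & " if isinstance(e, And) else " | "
        # children rendered at prec+1 so nested same-operator trees keep
        # their parentheses and re-parse to the identical structure
        body = sep.join(render(c, prec + 1) for c in e.children)
        return f"({body})" if prec < parent_prec else body

    return render(expr, 0)


def compile_expr(
    expr: RuleExpression, index: Mapping[str, int] | None = None
) -> Callable:
    """Compile to a fast callable ``f(state) -> 0/1``.

    With ``index`` given, ``state`` is an indexable sequence and variables are
    resolved positionally; otherwise ``state`` is a mapping keyed by name.
    Used in simulation hot loops where tree walking is too slow.
    """

    def src(e: RuleExpression) -> str:
        if isinstance(e, Const):
            return "True" if e.value else "False"
        if isinstance(e, Var):
            key = index[e.name] if index is not None else repr(e.name)
            return f"_s[{key}]"
        if isinstance(e, Not):
            return f"(not {src(e.child)})"
        sep = " and " if isinstance(e, And) else " or "
        return "(" + sep.join(src(c) for c in e.children) + ")"

    return eval(f"lambda _s: 1 if {src(expr)} else 0", {"__builtins__": {}})


def truth_table_equal(a: RuleExpression, b: RuleExpression) -> bool:
    """Logical equivalence by exhaustive enumeration over the joint support."""
    names = sorted(support(a) | support(b))
    for values in itertools.product((0, 1), repeat=len(names)):
        state = dict(zip(names, values))
        if evaluate(a, state) != evaluate(b, state):
            return False
    return True
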