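"""Reading and writing BoolNet ``.bnet`` files.

Dialect: a ``targets, factors`` header, one ``name, expression`` rule per
line, ``#`` comments, case-sensitive names, operators ``!`` > ``&`` > ``|``
with parentheses, and the literals ``0``/``1``. Nodes whose name ends in
``_phenotype`` are flagged as phenotype outputs on parse.
"""

from __future__ import annotations

import re
from typing import List, Tuple

from .errors import (
    DuplicateTargetError,
    ModelSyntaxError,
    UndeclaredVariableError,
)
from .expressions import Const, RuleExpression, Var, Not, make_and, make_or, to_string
from .network import BooleanNetwork

__all__ = ["parse_bnet", "serialize_bnet", "parse_expression"]

_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])|(?P<op>[!&|()]))")

PHENOTYPE_SUFFIX = "_phenotype"


def _tokenize(text: str, line: int) -> List[Tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ModelSyntaxError(f"unexpected character {text[pos:].strip()[0]!r}", line)
            break
        pos = m.end()
        for kind in ("name", "const", "op"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val))
                break
    return tokens


class _Parser:
    """Recursive-descent parser for the rule grammar (| lowest, ! highest)."""

    def __init__(self, tokens, line):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> RuleExpression:
        expr = self.disjunction()
        if self.pos != len(self.tokens):
            raise ModelSyntaxError(f"trailing tokens after expression", self.line)
        return expr

    def disjunction(self) -> RuleExpression:
        terms = [self.conjunction()]
        while self.peek() == ("op", "|"):
            self.take()
            terms.append(self.conjunction())
        return make_or(terms)

    def conjunction(self) -> RuleExpression:
        terms = [self.unary()]
        while self.peek() == ("op", "&"):
            self.take()
            terms.append(self.unary())
        return make_and(terms)

    def unary(self) -> RuleExpression:
        kind, val = self.peek()
        if (kind, val) == ("op", "!"):
            self.take()
            return Not(self.unary())
        if (kind, val) == ("op", "("):
            self.take()
            inner = self.disjunction()
            if self.take() != ("op", ")"):
                raise ModelSyntaxError("missing closing parenthesis", self.line)
            return inner
        if kind == "const":
            self.take()
            return Const(val == "1")
        if kind == "name":
            self.take()
            return Var(val)
        raise ModelSyntaxError("expected a variable, constant, '!' or '('", self.line)


def parse_expression(text: str, line: int = 0) -> RuleExpression:
    """Parse a single rule expression such as ``!A & (B | C)``."""
    tokens = _tokenize(text, line)
    if not tokens:
        raise ModelSyntaxError("empty rule expression", line)
    return _Parser(tokens, line).parse()


def parse_bnet(text: str) -> BooleanNetwork:
    """Parse a ``.bnet`` document into a :class:`BooleanNetwork`.

    Raises :class:`ModelSyntaxError` (with line number),
    :class:`DuplicateTargetError` or :class:`UndeclaredVariableError`.
    """
    nodes: List[str] = []
    rules = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if re.fullmatch(r"targets\s*,\s*factors", line, flags=re.IGNORECASE):
                header_seen = True
                continue
            raise ModelSyntaxError("expected 'targets, factors' header", lineno)
        if "," not in line:
            raise ModelSyntaxError("expected 'target, factors' rule line", lineno)
        name, expr_text = line.split(",", 1)
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z0-9_]+", name):
            raise ModelSyntaxError(f"invalid target name {name!r}", lineno)
        if name in rules:
            raise DuplicateTargetError(f"duplicate target {name!r} (line {lineno})")
        rules[name] = parse_expression(expr_text, lineno)
        nodes.append(name)
    if not header_seen:
        raise ModelSyntaxError("empty document: missing 'targets, factors' header", 1)
    # totality / declaredness checks live in the BooleanNetwork constructor
    phenotypes = tuple(n for n in nodes if n.endswith(PHENOTYPE_SUFFIX))
    return BooleanNetwork(nodes, rules, phenotypes)


def serialize_bnet(net: BooleanNetwork) -> str:
    """Serialize to ``.bnet`` text; ``parse_bnet`` of the result round-trips."""
    lines = ["targets, factors"]
    for n in net.nodes:
        lines.append(f"{n}, {to_string(net.rules[n])}")
    return "\n".join(lines) + "\n"
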