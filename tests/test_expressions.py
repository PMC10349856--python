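"""Expression semantics: evaluation, folding, printing."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from raflsbool.bnet import parse_expression
from raflsbool.errors import UnboundVariableError
from raflsbool.expressions import (
    And,
    Const,
    Not,
    Or,
    Var,
    compile_expr,
    evaluate,
    simplify,
    support,
    to_string,
    truth_table_equal,
)

NAMES = ("a", "b", "c", "d")


def expressions(max_leaves=6):
    leaf = st.one_of(
        st.sampled_from(NAMES).map(Var),
        st.booleans().map(Const),
    )
    return st.recursive(
        leaf,
        lambda sub: st.one_of(
            sub.map(Not),
            st.lists(sub, min_size=2, max_size=3).map(lambda cs: And(tuple(cs))),
            st.lists(sub, min_size=2, max_size=3).map(lambda cs: Or(tuple(cs))),
        ),
        max_leaves=max_leaves,
    )


@pytest.mark.parametrize(
    "text,state,expected",
    [
        # dominant-negative inhibition: CAV1 on blocks apoptosis despite all activators
        (
            "!CAV1_rna & (CASP3_phosphorylated | CASP8 | TNFRSF10A_rna | TNFRSF10B_rna)",
            dict.fromkeys(
                ["CAV1_rna", "CASP3_phosphorylated", "CASP8", "TNFRSF10A_rna", "TNFRSF10B_rna"], 1
            ),
            0,
        ),
        # the original OR form is always on once any activator (or !CAV1) fires
        (
            "!CAV1_rna | CASP3_phosphorylated | CASP8 | TNFRSF10A_rna | TNFRSF10B_rna",
            dict.fromkeys(
                ["CAV1_rna", "CASP3_phosphorylated", "CASP8", "TNFRSF10A_rna", "TNFRSF10B_rna"], 1
            ),
            1,
        ),
        (
            "!CAV1_rna & (CASP3_phosphorylated | CASP8 | TNFRSF10A_rna | TNFRSF10B_rna)",
            {"CAV1_rna": 0, "CASP8": 1, "CASP3_phosphorylated": 0, "TNFRSF10A_rna": 0, "TNFRSF10B_rna": 0},
            1,
        ),
        ("!a", {"a": 0}, 1),
        ("0 | a & b", {"a": 1, "b": 0}, 0),
    ],
)
def test_evaluate_examples(text, state, expected):
    assert evaluate(parse_expression(text), state) == expected


def test_evaluate_unbound_variable_raises():
    with pytest.raises(UnboundVariableError):
        evaluate(Var("missing"), {})


@settings(derandomize=True, max_examples=200, deadline=None)
@given(expressions())
def test_evaluate_agrees_with_compiled_form(expr):
    names = sorted(support(expr))
    index = {n: i for i, n in enumerate(names)}
    f = compile_expr(expr, index)
    for values in itertools.product((0, 1), repeat=len(names)):
        state = dict(zip(names, values))
        assert evaluate(expr, state) == f(list(values))


@settings(derandomize=True, max_examples=200, deadline=None)
@given(expressions())
def test_simplify_is_equivalent_and_fold_complete(expr):
    s = simplify(expr)
    assert truth_table_equal(expr, s)

    def no_const_children(e):
        if isinstance(e, (Const, Var)):
            return True
        if isinstance(e, Not):
            return not isinstance(e.child, Const) and no_const_children(e.child)
        return all(
            not isinstance(c, Const) and no_const_children(c) for c in e.children
        )

    assert no_const_children(s)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(expressions())
def test_print_parse_round_trip(expr):
    assert parse_expression(to_string(expr)) == expr


@pytest.mark.parametrize(
    "expr,expected",
    [
        (And((Const(True), Var("x"))), Var("x")),
        (Or((Const(True), Var("x"))), Const(True)),
        (Not(Const(False)), Const(True)),
        (And((Const(False), Var("x"), Var("y"))), Const(False)),
    ],
)
def test_constant_folding_laws(expr, expected):
    assert simplify(expr) == expected


def test_arity_invariants_enforced():
    with pytest.raises(ValueError):
        And((Var("a"),))
    with pytest.raises(ValueError):
        Or(())
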