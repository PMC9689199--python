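"""Symbolic kernel: grammar round-trip, traveling-wave reduction, derivative
elimination, coefficient collection."""

import sympy as sp
import pytest
from hypothesis import given, settings, strategies as st

from sesm import (
    EquationSpec,
    ExpressionError,
    collect_coefficients,
    make_simple_equation,
    parse_expression,
    reduce_derivatives,
    serialize_expression,
    substitute_traveling_wave,
)

xi = sp.Symbol("xi")


CORPUS = [
    "tanh(a*xi)^2",
    "a*V + b*V^k",
    "2/cosh(x - 4*t)^2",
    "exp(a*(k-1)*(xi+xi0))/(1 - b*exp(a*(k-1)*(xi+xi0)))",
    "-b/(2*a) - sqrt(b^2 - 4*a*c)/(2*a)*tanh(sqrt(b^2-4*a*c)*(xi+xi0)/2)",
    "4*arctan(A*exp(alpha*x + gamma*t))",
    "sn(xi, 1/2) + cn(xi, 1/2)*dn(xi, 1/2)",
    "3/7 + x^(2/3) - 5*x*y/11",
]


@pytest.mark.parametrize("text", CORPUS)
def test_parse_serialize_roundtrip(text):
    e = parse_expression(text)
    assert parse_expression(serialize_expression(e)) == e


@st.composite
def grammar_exprs(draw):
    syms = [sp.Symbol(s) for s in ("x", "y", "a", "b")]
    atoms = st.one_of(
        st.sampled_from(syms),
        st.integers(-9, 9).map(sp.Integer),
        st.tuples(st.integers(1, 9), st.integers(1, 9)).map(lambda t: sp.Rational(*t)),
    )
    fns = st.sampled_from([sp.exp, sp.tanh, sp.sin, sp.cosh, sp.atan])
    expr = draw(
        st.recursive(
            atoms,
            lambda inner: st.one_of(
                st.tuples(inner, inner).map(lambda t: t[0] + t[1]),
                st.tuples(inner, inner).map(lambda t: t[0] * t[1]),
                st.tuples(inner, st.integers(1, 3)).map(lambda t: t[0] ** t[1]),
                st.tuples(fns, inner).map(lambda t: t[0](t[1])),
            ),
            max_leaves=8,
        )
    )
    return expr


@given(grammar_exprs())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_roundtrip_property(expr):
    assert parse_expression(serialize_expression(expr)) == expr


def test_rationalized_literals():
    e = parse_expression("0.5*x + 0.25")
    assert not e.atoms(sp.Float)
    assert e == sp.Rational(1, 2) * sp.Symbol("x") + sp.Rational(1, 4)


def test_parse_errors():
    with pytest.raises(ExpressionError):
        parse_expression("frobnicate(x)")
    with pytest.raises(ExpressionError):
        parse_expression("x +* y")
    with pytest.raises(ExpressionError):
        parse_expression("; only a comment")


def test_equation_spec_rejects_undeclared_symbols():
    with pytest.raises(ExpressionError):
        EquationSpec.from_text("mystery*Q(xi)", "Q", ["xi"], parameters=[])


def test_traveling_wave_single_derivative():
    eq = EquationSpec.from_text(
        "Derivative(u(x,t),t)", "u", ["x", "t"], parameters=[]
    )
    ode = substitute_traveling_wave(eq, {"x": 1, "t": "-v"})
    U = sp.Function("u")(xi)
    assert ode.lhs == -sp.Symbol("v") * sp.Derivative(U, xi)


def test_traveling_wave_matches_direct_chain_rule(kdv_plus):
    """Independent oracle: substitute u(x,t) = U(x - v t) directly and let the
    CAS differentiate, then compare with the structural rewrite."""
    v, x, t = sp.symbols("v x t")
    U = sp.Function("u")
    direct = kdv_plus.lhs.subs(sp.Function("u")(x, t), U(x - v * t)).doit()
    direct = direct.subs(x - v * t, xi)
    ode = substitute_traveling_wave(kdv_plus, {"x": 1, "t": "-v"})
    assert sp.simplify(ode.lhs - direct) == 0


@pytest.mark.parametrize("n", [1, 2, 3])
def test_traveling_wave_linear_combination_coefficients(n):
    """An n-th order t/x derivative pair picks up the factor β + α(−v)ⁿ."""
    v = sp.Symbol("v")
    alpha, beta = sp.symbols("alphan betan")
    eq = EquationSpec.from_text(
        f"alphan*Derivative(Q(x,t),{','.join(['t']*n)}) + betan*Derivative(Q(x,t),{','.join(['x']*n)})",
        "Q", ["x", "t"], parameters=["alphan", "betan"],
    )
    ode = substitute_traveling_wave(eq, {"x": 1, "t": "-v"})
    Q = sp.Function("Q")(xi)
    expected = (beta + alpha * (-v) ** n) * sp.Derivative(Q, (xi, n))
    assert sp.expand(ode.lhs - expected) == 0


def test_reduce_riccati_second_derivative():
    se = make_simple_equation("riccati", {"a": "a", "b": "b", "c": "c"})
    V = sp.Function("V")(xi)
    pf = reduce_derivatives(sp.Derivative(V, xi, 2), se)
    a, b, c = sp.symbols("a b c")
    g = pf.gen
    oracle = sp.expand((2 * a * g + b) * (a * g**2 + b * g + c))
    assert sp.expand(pf.expand() - oracle) == 0


def test_reduce_bernoulli_first_derivative_is_definition():
    se = make_simple_equation("bernoulli", {"a": "a", "b": "b", "k": 2})
    V = sp.Function("V")(xi)
    pf = reduce_derivatives(sp.Derivative(V, xi), se)
    a, b = sp.symbols("a b")
    assert sp.expand(pf.expand() - (a * pf.gen + b * pf.gen**2)) == 0


def test_reduce_squared_family_second_derivative():
    """(V′)² = Σ aⱼVʲ implies V″ = ½ Σ j aⱼ V^{j−1}."""
    coeffs = [sp.Symbol(f"A{j}") for j in range(4)]
    se = make_simple_equation("squared_poly", {"l": 2, "coeffs": coeffs})
    V = sp.Function("V")(xi)
    pf = reduce_derivatives(sp.Derivative(V, xi, 2), se)
    g = pf.gen
    oracle = sum(sp.Rational(j, 2) * coeffs[j] * g ** (j - 1) for j in range(1, 4))
    assert sp.expand(pf.expand() - sp.expand(oracle)) == 0


@pytest.mark.parametrize("order", [2, 3, 4])
def test_squared_family_keeps_first_derivative_to_power_one(order):
    coeffs = [1, 0, -1, sp.Rational(1, 3)]
    se = make_simple_equation("squared_poly", {"l": 2, "coeffs": coeffs})
    V = sp.Function("V")(xi)
    pf = reduce_derivatives(sp.Derivative(V, xi, order) * sp.Derivative(V, xi), se)
    assert all(j in (0, 1) for _, j in pf.coeffs)


def test_reduction_matches_concrete_solution_oracle():
    """Independent oracle: V = tan(ξ) solves the Riccati V′ = V² + 1, so the
    reduced polynomial evaluated at tan(ξ) must equal direct CAS
    differentiation of the original expression."""
    se = make_simple_equation("riccati", {"a": 1, "b": 0, "c": 1})
    V = sp.Function("V")
    expr = V(xi) ** 2 * sp.Derivative(V(xi), xi, 2) + sp.Derivative(V(xi), xi, 3)
    pf = reduce_derivatives(expr, se)
    tan = sp.tan(xi)
    direct = expr.subs(V(xi), tan).doit()
    assert sp.simplify(sp.expand_trig(sp.expand(pf.expand().subs(pf.gen, tan) - direct))) == 0


def test_collect_reconstruction(fisher_ode):
    from sesm import Ansatz, build_system

    se = make_simple_equation("bernoulli", {"a": "a", "b": "b", "k": 2})
    V = sp.Function("V")(xi)
    ansatz = Ansatz(degree=2, coeff="a")
    expr = fisher_ode.lhs.replace(
        lambda e: isinstance(e, sp.Derivative),
        lambda d: sp.Derivative(ansatz.expression(V), *d.variable_count),
    ).subs(sp.Function("Q")(xi), ansatz.expression(V)).doit()
    pf = reduce_derivatives(expr, se)
    system = collect_coefficients(pf)
    rebuilt = sum(
        rel * pf.gen**i for (i, j), rel in zip(sorted(pf.coeffs, key=lambda k: (-k[0], -k[1])), [])
    )
    # reconstruction: sum over the polynomial form itself equals the reduction
    assert sp.expand(pf.expand() - sum(c * pf.gen**i for (i, _), c in pf.coeffs.items())) == 0
    # every relation is V- and xi-free
    assert all(not r.has(pf.gen) and not r.has(xi) for r in system.relations)


def test_collect_zero_expression_gives_empty_system():
    from sesm.expressions import PolynomialForm

    pf = PolynomialForm(sp.Symbol("_V"), None, {(0, 0): sp.Integer(0)})
    assert len(collect_coefficients(pf)) == 0


def test_laurent_mode_allows_negative_powers():
    from sesm.expressions import PolynomialForm

    pf = PolynomialForm(sp.Symbol("_V"), None, {(-1, 0): sp.Symbol("a")}, laurent=True)
    assert pf.expand() == sp.Symbol("a") / sp.Symbol("_V")
    with pytest.raises(ExpressionError):
        PolynomialForm(sp.Symbol("_V"), None, {(-1, 0): sp.Symbol("a")})
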