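"""Solver pipeline: balance equations, system generation, symbolic solving,
assembly and residual verification."""

from fractions import Fraction

import sympy as sp
import pytest

from sesm import (
    Ansatz,
    EquationSpec,
    build_product_system,
    build_system,
    compute_balance,
    derive_equation_constraints,
    gkdv_composite_solution,
    make_simple_equation,
    solve_system,
    verify_solution,
)
from sesm.engine import (
    bernoulli_exponent,
    camassa_holm_balance,
    rayleigh_degree,
    riccati_ansatz_degree,
    sir_simple_equation_degree,
    smallest_admissible_degree,
    swift_hohenberg_degree,
)

xi = sp.Symbol("xi")
S = sp.Symbol


def _poly_wave_ode(N, M):
    terms = [f"nu{n}*Derivative(Q(xi),{','.join(['xi'] * n)})" for n in range(1, N + 1)]
    terms += [f"mu{m}*Q(xi)^{m}" if m > 1 else "mu1*Q(xi)" for m in range(1, M + 1)]
    params = [f"nu{n}" for n in range(1, N + 1)] + [f"mu{m}" for m in range(1, M + 1)]
    return EquationSpec.from_text(" + ".join(terms), "Q", ["xi"], parameters=params)


@pytest.mark.parametrize("M", [2, 3, 4, 5])
def test_generic_balance_reproduces_bernoulli_formula(M):
    """Admissible (L, k) pairs from top-degree search coincide with the
    closed-form rule k = 1 + L(M−1)/N on an integer grid."""
    N = 2
    eq = _poly_wave_ode(N, M)
    found = {(c.ansatz_degree, c.simple_degree) for c in compute_balance(eq, range(1, 9), range(2, 9))}
    predicted = set()
    for L in range(1, 9):
        k = bernoulli_exponent(L, M, N)
        if k.denominator == 1 and 2 <= k <= 8:
            predicted.add((L, int(k)))
    assert found == predicted


def test_generic_balance_riccati_rule():
    """With β = 2 the admissible ansatz degree satisfies L(M−1) = N."""
    for M in (2, 3, 5):
        eq = _poly_wave_ode(2, M)
        found = [c.ansatz_degree for c in compute_balance(eq, range(1, 9), [2])]
        L = riccati_ansatz_degree(M, 2)
        expected = [int(L)] if L.denominator == 1 else []
        assert found == expected


def test_printed_balance_formulas():
    assert bernoulli_exponent(2, 2, 2) == 2
    assert sir_simple_equation_degree(1, 2) == 2
    assert swift_hohenberg_degree(2, 5) == 1
    assert swift_hohenberg_degree(3, 5) == 2
    assert rayleigh_degree(2, 3, 3) == 4
    assert camassa_holm_balance(3, 2, 2) == 2
    assert smallest_admissible_degree(2, 2, above=2) == 4
    # degree 3 is skipped precisely because k would be fractional
    assert bernoulli_exponent(3, 2, 2) == Fraction(5, 2)


def test_build_system_matches_printed_relation_set(fisher_ode):
    se = make_simple_equation("bernoulli", {"a": "a", "b": "b", "k": 2})
    system = build_system(fisher_ode, Ansatz(degree=2, coeff="a"), se)
    a0, a1, a2, a, b = sp.symbols("a0 a1 a2 a b")
    nu1, nu2, mu1, mu2 = sp.symbols("nu1 nu2 mu1 mu2")
    expected = [
        6 * nu1 * a2 * b**2 + mu2 * a2**2,
        2 * nu2 * a2 * b + 10 * nu1 * a2 * b * a + 2 * mu2 * a2 * a1 + 2 * nu1 * a1 * b**2,
        mu1 * a2 + mu2 * a1**2 + 2 * nu2 * a2 * a + nu2 * a1 * b + 4 * nu1 * a2 * a**2
        + 2 * mu2 * a2 * a0 + 3 * nu1 * a1 * a * b,
        mu1 * a1 + 2 * mu2 * a1 * a0 + nu1 * a1 * a**2 + nu2 * a1 * a,
        mu1 * a0 + mu2 * a0**2,
    ]
    assert len(system) == 5
    for got, want in zip(system.relations, expected):
        assert sp.expand(got - want) == 0


def test_solve_system_contains_printed_tuple(fisher_ode):
    se = make_simple_equation("bernoulli", {"a": "a", "b": "b", "k": 2})
    system = build_system(fisher_ode, Ansatz(degree=2, coeff="a"), se)
    a0, a1, a2, a = sp.symbols("a0 a1 a2 a")
    nu1, nu2, mu1, mu2, b = sp.symbols("nu1 nu2 mu1 mu2 b")
    sols = solve_system(system, unknowns=[a0, a1, a2, a, S("mu1")], hints={a1: 0})
    assert any(s.trivial for s in sols)
    wanted = {
        a0: 6 * nu2**2 / (25 * nu1 * mu2),
        a1: sp.Integer(0),
        a2: -6 * nu1 * b**2 / mu2,
        a: -nu2 / (5 * nu1),
        S("mu1"): -6 * nu2**2 / (25 * nu1),
    }
    assert any(
        all(sp.simplify(s.as_dict.get(k, k) - v) == 0 for k, v in wanted.items())
        for s in sols if not s.trivial
    )


def test_solve_system_simple_polynomial():
    from sesm.expressions import AlgebraicSystem

    x = S("x")
    system = AlgebraicSystem((x**2 - 1,), (x,))
    sols = solve_system(system, trivial_markers=[])
    vals = sorted(s.as_dict[x] for s in sols)
    assert vals == [-1, 1]


def test_unbalanced_configuration_is_flagged_not_dropped(fisher_ode):
    """An inadmissible degree yields a single-product top relation that forces
    an ansatz coefficient to zero; it must be kept in the system."""
    se = make_simple_equation("bernoulli", {"a": "a", "b": "b", "k": 2})
    system = build_system(fisher_ode, Ansatz(degree=1, coeff="a"), se)
    tops = [r for r in system.relations if len(sp.Add.make_args(sp.expand(r))) == 1]
    assert tops, "expected a one-term relation in the unbalanced system"


def test_camassa_holm_system_sizes():
    base = (
        "(p1 - v)*Derivative(U(xi),xi) + p2*v*Derivative(U(xi),xi,xi,xi)"
        " - p3*Derivative(q1*U(xi) + q2*U(xi)^2, xi, xi, xi)"
        " + p4*Derivative({flux}/2 + p5*q2*Derivative(U(xi),xi)^2, xi)"
    )
    params = ["v", "p1", "p2", "p3", "p4", "p5", "q1", "q2", "r1", "r2", "r3"]
    ans = Ansatz(degree=2, coeff="theta")

    eq_b = EquationSpec.from_text(
        base.format(flux="(r1*U(xi) + r2*U(xi)^2 + r3*U(xi)^3)"), "U", ["xi"], params)
    se_b = make_simple_equation("bernoulli", {"a": "a", "b": "b", "k": 2})
    assert len(build_system(eq_b, ans, se_b)) == 7

    eq_r = EquationSpec.from_text(base.format(flux="r1*U(xi)"), "U", ["xi"], params)
    se_r = make_simple_equation("riccati", {"a": "a", "b": "b", "c": "c"})
    assert len(build_system(eq_r, ans, se_r)) == 8

    eq_t = EquationSpec.from_text(
        base.format(flux="(r1*U(xi) + r2*U(xi)^2)"), "U", ["xi"], params)
    se_t = make_simple_equation("riccati", {"a": "a", "b": 0, "c": "c"})
    assert len(build_system(eq_t, ans, se_t)) == 8


def test_inverse_construction_system_sizes():
    se = make_simple_equation("extended_tanh", {"abar": "a", "cbar": "b"})
    t_lin = EquationSpec.from_text(
        "q1*Derivative(F(xi),xi,xi) + q2*F(xi)*Derivative(F(xi),xi) + q3*F(xi)^3"
        " + q4*F(xi)^2 + q5*F(xi) + q6",
        "F", ["xi"], parameters=["q1", "q2", "q3", "q4", "q5", "q6"])
    assert len(derive_equation_constraints(t_lin, Ansatz(degree=1, coeff="p"), se)) == 4
    t_quad = EquationSpec.from_text(
        "q1*Derivative(F(xi),xi,xi) + q2*F(xi)*Derivative(F(xi),xi) + q3*Derivative(F(xi),xi)"
        " + q4*F(xi)^3 + q5*F(xi)^2 + q6*F(xi) + q7",
        "F", ["xi"], parameters=["q1", "q2", "q3", "q4", "q5", "q6", "q7"])
    assert len(derive_equation_constraints(t_quad, Ansatz(degree=2, coeff="p"), se)) == 7


def test_gkdv_chain_classical_specialization(kdv_minus):
    res = gkdv_composite_solution(1, -6, 1, -2)
    assert res["mu"] == 1 and res["nu"] == -4
    x, t = sp.symbols("x t")
    assert sp.simplify(res["u"] + 2 / sp.cosh(x - 4 * t) ** 2) == 0
    assert verify_solution(kdv_minus, res["u"]).passed


def test_gkdv_chain_general_power():
    res = gkdv_composite_solution(3, 2, 1, 1)
    eq = EquationSpec.from_text(
        "Derivative(u(x,t),t) + 2*u(x,t)^3*Derivative(u(x,t),x) + Derivative(u(x,t),x,x,x)",
        "u", ["x", "t"])
    assert verify_solution(eq, res["u"]).passed


def test_verify_solution_rejects_corrupted_coefficient(kdv_minus):
    x, t = sp.symbols("x t")
    rep = verify_solution(kdv_minus, -3 / sp.cosh(x - 4 * t) ** 2)
    assert not rep.passed and rep.max_relative_residual > 1e-6


def test_product_ansatz_system_and_solution():
    """Separable product ansatz for the squared-second-derivative equation:
    the system annihilates under p=w=r=s=0 with the balancing q, and the
    assembled arctan-exponential solves the original equation."""
    from sesm import apply_transform, match_transform

    eq = EquationSpec.from_text(
        "b*Derivative(u(x,t),x,x)^2 + d*Derivative(u(x,t),t,t)^2 - l*sin(u(x,t))^2",
        "u", ["x", "t"], parameters=["b", "d", "l"])
    out, _ = apply_transform(eq, [c for c in match_transform(eq) if c.id == 2][0])
    A, alpha, gamma = sp.symbols("A alpha gamma")
    p, q, r, s, v, w = sp.symbols("p q r s v w")
    se_x = make_simple_equation(
        "squared_poly", {"l": 2, "coeffs": [r * alpha**2, 0, q * alpha**2, 0, p * alpha**2]},
        unknown="T1", var="x")
    se_t = make_simple_equation(
        "squared_poly", {"l": 2, "coeffs": [w * gamma**2, 0, v * gamma**2, 0, s * gamma**2]},
        unknown="T2", var="t")
    system = build_product_system(out, A, se_x, se_t)
    assert len(system) == 9
    b, d, l = sp.symbols("b d l")
    qsol = sp.sqrt(l - d * gamma**4 * v**2) / (sp.sqrt(b) * alpha**2)
    assignment = {p: 0, w: 0, r: 0, s: 0, q: qsol}
    assert system.is_satisfied_by(assignment)
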