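"""Solver pipeline: ansatz construction, balance equations, algebraic-system
generation and solving, solution assembly, and residual verification.

The pipeline mirrors the standard auxiliary-equation workflow for traveling
waves: reduce the PDE to an ODE in ξ, pose the solution as a polynomial of
the auxiliary ODE's solution V, eliminate derivatives through the auxiliary
equation, collect powers of V, and solve the resulting nonlinear algebraic
system for the ansatz coefficients.  The *balance equation* (top-degree
matching) fixes the admissible combinations of ansatz degree and
auxiliary-equation degree; a combination is admissible when the maximal
V-degree of the reduced equation is attained by at least two terms, so the
leading coefficient relation can vanish nontrivially.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import sympy as sp

from .expressions import (
    AlgebraicSystem,
    EquationSpec,
    ExpressionError,
    PolynomialForm,
    collect_coefficients,
    reduce_derivatives,
)
from .simple_equations import SimpleEquation, SolutionBranch, make_simple_equation

__all__ = [
    "Ansatz",
    "BalanceCandidate",
    "ParameterSolution",
    "ExactSolution",
    "VerificationReport",
    "compute_balance",
    "build_system",
    "build_product_system",
    "solve_system",
    "assemble_solution",
    "verify_solution",
    "derive_equation_constraints",
    "bernoulli_exponent",
    "riccati_ansatz_degree",
    "sir_simple_equation_degree",
    "camassa_holm_balance",
    "swift_hohenberg_degree",
    "rayleigh_degree",
    "smallest_admissible_degree",
    "gkdv_composite_solution",
]

DEFAULT_SEED = 1653


# ---------------------------------------------------------------------------
# ansatz
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ansatz:
    """A power-series ansatz u(ξ) = Σ_{μ=low}^{degree} θ_μ V(ξ)^μ.

    ``low`` may be negative (Laurent mode).  Coefficient symbols are
    ``<coeff><μ>``; the symbol for negative μ is ``<coeff>m<|μ|>``.
    """

    degree: int
    low: int = 0
    coeff: str = "theta"

    def __post_init__(self) -> None:
        if self.degree < self.low:
            raise ExpressionError("ansatz degree below lowest power")

    @property
    def coefficients(self) -> tuple[sp.Symbol, ...]:
        return tuple(self.symbol(i) for i in range(self.low, self.degree + 1))

    def symbol(self, i: int) -> sp.Symbol:
        return sp.Symbol(f"{self.coeff}{i}" if i >= 0 else f"{self.coeff}m{-i}")

    def expression(self, V: sp.Expr) -> sp.Expr:
        return sum(self.symbol(i) * V**i for i in range(self.low, self.degree + 1))

    @property
    def laurent(self) -> bool:
        return self.low < 0


# ---------------------------------------------------------------------------
# balance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BalanceCandidate:
    """An integer assignment of (ansatz degree L, auxiliary degree β) together
    with the top V-degree it produces and how many terms attain it."""

    ansatz_degree: int
    simple_degree: int
    max_degree: int
    top_terms: int

    @property
    def admissible(self) -> bool:
        return self.top_terms >= 2


def _term_degree(term: sp.Expr, u_applied: sp.Expr, L: sp.Symbol, beta: sp.Symbol) -> sp.Expr | None:
    """Top V-degree of one additive term as an affine expression in (L, β).

    Powers of the unknown contribute e·L; an e-th power of an n-th derivative
    contributes e·(L + n(β−1)).  Returns None for terms not involving the
    unknown (degree 0).
    """
    deg = sp.Integer(0)
    found = False
    for factor in sp.Mul.make_args(term):
        base, e = factor.as_base_exp()
        if base == u_applied:
            deg += e * L
            found = True
        elif isinstance(base, sp.Derivative) and base.expr == u_applied:
            n = sum(int(o) for _, o in base.variable_count)
            deg += e * (L + n * (beta - 1))
            found = True
    return deg if found else None


def compute_balance(
    eq: EquationSpec,
    ansatz_degrees: Iterable[int],
    simple_degrees: Iterable[int],
) -> list[BalanceCandidate]:
    """All admissible (L, β) pairs within the given integer bounds.

    ``eq`` must be an ODE in one variable.  Every returned candidate makes the
    maximal V-degree of the reduced equation be attained by at least two
    additive terms (the nontriviality requirement); the full list is returned
    because a non-minimal admissible degree can still carry solutions whose
    surplus coefficients are zeroed by the algebraic system.
    """
    if len(eq.independent_vars) != 1:
        raise ExpressionError("balance computation expects a single-variable ODE")
    L, beta = sp.symbols("_L _beta")
    u = eq.applied_unknown
    lhs = sp.expand(eq.lhs.doit())
    degs = [d for t in sp.Add.make_args(lhs) if (d := _term_degree(t, u, L, beta)) is not None]
    # group identical degree expressions (several monomials of one structural
    # term share a degree; they count once toward the attainment count)
    unique = list(dict.fromkeys(sp.expand(d) for d in degs))
    out = []
    for Lv in ansatz_degrees:
        for bv in simple_degrees:
            vals = [int(d.subs({L: Lv, beta: bv})) for d in unique]
            mx = max(vals)
            top = sum(1 for v in vals if v == mx)
            if top >= 2:
                out.append(BalanceCandidate(Lv, bv, mx, top))
    return sorted(out, key=lambda c: (c.ansatz_degree, c.simple_degree))


# printed balance relations for the equation families in the catalog --------


def bernoulli_exponent(L: int, M: int, N: int) -> Fraction:
    """Bernoulli exponent k = 1 + L(M−1)/N balancing an N-th order ODE with
    top nonlinearity Q^M under an ansatz of degree L."""
    return 1 + Fraction(L * (M - 1), N)


def riccati_ansatz_degree(M: int, N: int) -> Fraction:
    """Ansatz degree from L(M−1) = N when the auxiliary equation is Riccati."""
    return Fraction(N, M - 1)


def sir_simple_equation_degree(K: int, M: int) -> int:
    """Auxiliary-equation degree L = K(M−1) + 1 for the reduced recovered-count
    ODE truncated at order M, under an ansatz of degree K."""
    return K * (M - 1) + 1


def camassa_holm_balance(J: int, I: int, k: int) -> Fraction:
    """Ansatz degree ν₁ = 2(k−1)/(J−I) for the generalized Camassa–Holm
    equation with flux degrees J > I and Bernoulli exponent k."""
    return Fraction(2 * (k - 1), J - I)


def swift_hohenberg_degree(beta: int, s_star: int) -> Fraction:
    """Ansatz degree η = 4(β−1)/(s*−1) for the generalized Swift–Hohenberg
    equation with top nonlinearity u^{s*}."""
    return Fraction(4 * (beta - 1), s_star - 1)


def rayleigh_degree(m: int, beta: int, s_star: int) -> Fraction:
    """Ansatz degree η = m(β−1)/(s*−m) for the generalized Rayleigh equation
    with velocity-polynomial degree m and top nonlinearity u^{s*}."""
    return Fraction(m * (beta - 1), s_star - m)


def smallest_admissible_degree(N: int, M: int, above: int = 2, limit: int = 64) -> int:
    """Smallest ansatz degree L > ``above`` for which the Bernoulli exponent
    k = 1 + L(M−1)/N is an integer (> 1)."""
    for L in range(above + 1, limit + 1):
        k = bernoulli_exponent(L, M, N)
        if k.denominator == 1 and k > 1:
            return L
    raise ExpressionError("no admissible degree within limit")


# ---------------------------------------------------------------------------
# system generation
# ---------------------------------------------------------------------------


def _substitute_ansatz(eq: EquationSpec, ansatz_expr: sp.Expr) -> sp.Expr:
    u = eq.applied_unknown
    lhs = eq.lhs.replace(
        lambda e: isinstance(e, sp.Derivative) and e.expr == u,
        lambda d: sp.Derivative(ansatz_expr, *d.variable_count),
    )
    return lhs.subs(u, ansatz_expr).doit()


def build_system(
    eq: EquationSpec,
    ansatz: Ansatz,
    se: SimpleEquation,
) -> AlgebraicSystem:
    """Generate the algebraic system for a power-series ansatz over one
    auxiliary equation: substitute, eliminate derivatives, collect V-powers.

    Relations are ordered by descending V-degree.  A relation consisting of a
    single product is kept and flagged via ``AlgebraicSystem`` inspection by
    the caller (it forces an ansatz coefficient to vanish — an unbalanced
    configuration), never silently dropped.
    """
    if len(eq.independent_vars) != 1:
        raise ExpressionError("build_system expects an ODE in the wave coordinate")
    xi = sp.Symbol(eq.independent_vars[0])
    if se.var != eq.independent_vars[0]:
        se = SimpleEquation(se.family, se.params, se.unknown, eq.independent_vars[0])
    Vf = sp.Function(se.unknown)(xi)
    expr = _substitute_ansatz(eq, ansatz.expression(Vf))
    pf = reduce_derivatives(expr, se, xi=xi, laurent=ansatz.laurent)
    system = collect_coefficients(pf)
    unknowns = tuple(c for c in ansatz.coefficients if any(r.has(c) for r in system.relations))
    params = tuple(
        s for s in sorted({s for r in system.relations for s in r.free_symbols}, key=str)
        if s not in unknowns
    )
    return AlgebraicSystem(system.relations, unknowns or ansatz.coefficients, params)


def build_product_system(
    eq: EquationSpec,
    amplitude: sp.Symbol,
    se_x: SimpleEquation,
    se_t: SimpleEquation,
) -> AlgebraicSystem:
    """Algebraic system for a separable product ansatz F = A·T₁(αx)·T₂(γt)
    where T₁, T₂ each satisfy a squared-derivative auxiliary equation.

    ``se_x``/``se_t`` must be squared-polynomial families; their scaling
    symbols are the wave-number/frequency parameters α, γ declared in their
    ``var`` fields as ``("x", alpha)``-style tuples is not supported — instead
    the chain factors are passed through the equation's variables: the
    equation must already be written in the scaled arguments.
    """
    if len(eq.independent_vars) != 2:
        raise ExpressionError("product ansatz expects two independent variables")
    xv, tv = (sp.Symbol(v) for v in eq.independent_vars)
    F = eq.applied_unknown
    T1 = sp.Function("T1")(xv)
    T2 = sp.Function("T2")(tv)
    expr = eq.lhs.replace(
        lambda e: isinstance(e, sp.Derivative) and e.expr == F,
        lambda d: sp.Derivative(amplitude * T1 * T2, *d.variable_count),
    )
    expr = expr.subs(F, amplitude * T1 * T2).doit()

    V1, W1 = sp.symbols("_T1 _T1p")
    V2, W2 = sp.symbols("_T2 _T2p")
    from .expressions import _squared_family_derivative_table

    max_order = 0
    for d in expr.atoms(sp.Derivative):
        max_order = max(max_order, sum(int(o) for _, o in d.variable_count))
    tab1 = _squared_family_derivative_table(se_x.derivative_rule(V1), V1, W1, max_order)
    tab2 = _squared_family_derivative_table(se_t.derivative_rule(V2), V2, W2, max_order)

    def repl(d: sp.Derivative):
        n = sum(int(o) for _, o in d.variable_count)
        var = d.variable_count[0][0]
        return tab1[n] if var == xv else tab2[n]

    work = expr.replace(
        lambda e: isinstance(e, sp.Derivative)
        and isinstance(e.expr, sp.core.function.AppliedUndef),
        repl,
    ).subs({T1: V1, T2: V2})
    work = sp.expand(work)
    # reduce residual even powers of the first derivatives
    for V, W, se_ in ((V1, W1, se_x), (V2, W2, se_t)):
        if work.has(W):
            rhs = sp.expand(se_.derivative_rule(V))
            p = sp.Poly(work, W)
            work = sp.expand(sum(c * rhs ** (k // 2) * W ** (k % 2) for (k,), c in p.terms()))
    poly = sp.Poly(work, V1, W1, V2, W2)
    relations = []
    seen = []
    for mon, c in sorted(zip(poly.monoms(), poly.coeffs()), key=lambda mc: (-sum(mc[0]), mc[0])):
        c = sp.expand(c)
        if c != 0:
            relations.append(c)
            seen.append(mon)
    symbols = tuple(sorted({s for r in relations for s in r.free_symbols}, key=str))
    return AlgebraicSystem(tuple(relations), symbols)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSolution:
    """One assignment solving the algebraic system; ``trivial`` marks the
    all-zero ansatz."""

    assignment: tuple[tuple[sp.Symbol, sp.Expr], ...]
    trivial: bool = False

    @property
    def as_dict(self) -> dict[sp.Symbol, sp.Expr]:
        return dict(self.assignment)


def solve_system(
    system: AlgebraicSystem,
    unknowns: Sequence[sp.Symbol] | None = None,
    hints: Mapping[sp.Symbol, sp.Expr] | None = None,
    trivial_markers: Sequence[sp.Symbol] | None = None,
    verify: bool = True,
) -> list[ParameterSolution]:
    """Solve the nonlinear algebraic system symbolically.

    ``hints`` pre-assigns symbols (e.g. zeroing a surplus ansatz coefficient)
    before solving; they become part of every returned assignment.  Solutions
    are verified by back-substitution; assignments in which every
    ``trivial_markers`` symbol vanishes are flagged trivial, not dropped.
    """
    hints = dict(hints or {})
    unknowns = list(unknowns if unknowns is not None else system.unknowns)
    relations = [sp.expand(r.subs(hints)) for r in system.relations]
    relations = [r for r in relations if r != 0]
    solve_for = [u for u in unknowns if u not in hints]
    if not relations:
        sols = [{}]
    else:
        sols = sp.solve(relations, solve_for, dict=True)
    out = []
    for s in sols:
        full = dict(hints)
        full.update(s)
        if verify and not all(
            sp.simplify(sp.together(r.subs(full))) == 0 for r in system.relations
        ):
            continue
        markers = list(trivial_markers if trivial_markers is not None else system.unknowns)
        trivial = bool(markers) and all(sp.simplify(full.get(m, m)) == 0 for m in markers)
        out.append(
            ParameterSolution(tuple(sorted(full.items(), key=lambda kv: str(kv[0]))), trivial)
        )
    return out


# ---------------------------------------------------------------------------
# assembly and verification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExactSolution:
    """A closed-form solution with its validity conditions and provenance."""

    expr: sp.Expr
    variables: tuple[str, ...]
    conditions: tuple[sp.Expr, ...] = ()
    provenance: str = ""


@dataclass(frozen=True)
class VerificationReport:
    passed: bool
    symbolic_zero: bool
    max_relative_residual: float | None
    n_points: int
    note: str = ""


def assemble_solution(
    ansatz: Ansatz,
    branch: SolutionBranch,
    psol: ParameterSolution,
    extra_subs: Mapping[sp.Symbol, sp.Expr] | None = None,
    provenance: str = "",
) -> ExactSolution:
    """Closed form u(ξ) = Σ θ_μ V(ξ)^μ with the solved coefficients and the
    chosen solution branch of the auxiliary equation substituted in."""
    subs = dict(psol.as_dict)
    if extra_subs:
        subs.update(extra_subs)
    expr = ansatz.expression(branch.expr).subs(subs)
    conds = tuple(branch.conditions) + tuple(
        c.subs(subs) for c in getattr(branch.equation, "conditions", ())
    )
    return ExactSolution(sp.simplify(expr), (branch.equation.var,), conds, provenance)


def _substitute_solution(eq: EquationSpec, expr: sp.Expr) -> sp.Expr:
    u = eq.applied_unknown
    lhs = eq.lhs.replace(
        lambda e: isinstance(e, sp.Derivative) and e.expr == u,
        lambda d: sp.Derivative(expr, *d.variable_count),
    )
    return lhs.subs(u, expr).doit()


def _numeric_residual(
    residual: sp.Expr,
    variables: Sequence[sp.Symbol],
    witness: Mapping[sp.Symbol, sp.Expr],
    seed: int,
    digits: int,
    n_points: int,
) -> tuple[float, int]:
    rng = random.Random(seed)
    res = residual.subs(witness)
    terms = [t.subs(witness) for t in sp.Add.make_args(residual)]
    free = sorted(res.free_symbols | {s for t in terms for s in t.free_symbols}, key=str)
    missing = [s for s in free if s not in variables]
    if missing:
        raise ExpressionError(f"witness values required for parameters {missing}")
    max_rel = 0.0
    done = 0
    attempts = 0
    while done < n_points and attempts < 20 * n_points:
        attempts += 1
        point = {
            v: sp.Rational(rng.randint(-200, 200), 100) or sp.Rational(1, 7)
            for v in variables
        }
        try:
            vals = [sp.Abs(t.subs(point)).evalf(digits) for t in terms]
            rv = sp.Abs(res.subs(point)).evalf(digits)
        except (TypeError, ValueError, ZeroDivisionError):
            continue
        if not rv.is_number or any(not v.is_number for v in vals):
            continue
        scale = max([sp.Float(1, digits)] + vals)
        if scale > sp.Float("1e40"):
            continue  # too close to a pole
        max_rel = max(max_rel, float(sp.Abs(rv / scale)))
        done += 1
    return max_rel, done


def verify_solution(
    eq: EquationSpec,
    solution: ExactSolution | sp.Expr,
    witness: Mapping[sp.Symbol, sp.Expr] | None = None,
    seed: int = DEFAULT_SEED,
    digits: int = 50,
    n_points: int = 16,
    threshold: float = 1e-30,
    try_symbolic: bool = True,
) -> VerificationReport:
    """Certify a closed form: symbolic residual simplification first, then a
    high-precision numeric residual at sampled points.

    The numeric criterion is |residual| / max(1, largest term magnitude)
    below ``threshold`` at every successfully sampled point.
    """
    expr = solution.expr if isinstance(solution, ExactSolution) else solution
    residual = _substitute_solution(eq, expr)
    if witness:
        # a witness instance keeps the symbolic attempt tractable; the report
        # then certifies the residual at that instance
        residual = residual.subs(dict(witness))
        witness = {}
    if try_symbolic:
        simplified = sp.simplify(sp.together(sp.expand(residual)))
        if simplified == 0:
            return VerificationReport(True, True, 0.0, 0)
        simplified2 = sp.simplify(sp.radsimp(sp.powsimp(simplified, force=True)))
        if simplified2 == 0 or sp.factor(sp.cancel(simplified2)) == 0:
            return VerificationReport(True, True, 0.0, 0)
    variables = [sp.Symbol(v) for v in eq.independent_vars]
    try:
        max_rel, done = _numeric_residual(
            residual, variables, dict(witness or {}), seed, digits, n_points
        )
    except ExpressionError as exc:
        return VerificationReport(False, False, None, 0, str(exc))
    if done == 0:
        return VerificationReport(False, False, None, 0, "sampling hit singularities only")
    return VerificationReport(max_rel < threshold, False, max_rel, done)


def derive_equation_constraints(
    template: EquationSpec,
    ansatz: Ansatz,
    se: SimpleEquation,
) -> AlgebraicSystem:
    """Inverse direction: constrain a template ODE's symbolic coefficients so
    that the prescribed composite form solves it.

    The template is a polynomial ODE with unknown coefficients q_i; the
    returned system is in the q_i together with the ansatz coefficients and
    the auxiliary-equation parameters — any solution of it instantiates an
    equation having the composite form as an exact solution.
    """
    if not template.lhs.is_polynomial(template.applied_unknown):
        pass  # derivatives make is_polynomial unreliable; structural check below
    return build_system(template, ansatz, se)


# ---------------------------------------------------------------------------
# generalized-KdV composite chain
# ---------------------------------------------------------------------------


def gkdv_composite_solution(
    p: int,
    A: sp.Expr,
    b1: sp.Expr,
    Omega: sp.Expr,
) -> dict:
    """Solitary-wave solution of u_t + A uᵖ u_x + u_xxx = 0 through the
    composite chain u = b₁·g(ξ), (g′)² = a₂g² + a_{p+2}g^{p+2}, ξ = μx + νt.

    Matching the linear-degree ansatz fixes a₂ = −ν/μ³ and
    a_{p+2} = −2Ab₁ᵖ/(μ²(p+1)(p+2)); requiring the cosh-profile branch
    g = Ω·cosh^{−2/p}(ξ) (unit width) then pins
    μ² = p²·A·Ωᵖ·b₁ᵖ / (2(p+1)(p+2)) and ν = −4μ³/p².  Returns μ (positive
    root), ν, the auxiliary equation, and the solution u(x, t).
    """
    p = int(p)
    if p < 1:
        raise ExpressionError("p must be a positive integer")
    A, b1, Omega = sp.sympify(A), sp.sympify(b1), sp.sympify(Omega)
    mu2 = p**2 * A * Omega**p * b1**p / (2 * (p + 1) * (p + 2))
    mu = sp.sqrt(mu2)
    nu = -4 * mu**3 / p**2
    a2 = sp.simplify(-nu / mu**3)
    ap2 = sp.simplify(-2 * A * b1**p / (mu**2 * (p + 1) * (p + 2)))
    x, t = sp.symbols("x t")
    xi = mu * x + nu * t
    u = b1 * Omega * sp.cosh(xi) ** sp.Rational(-2, p)
    se = make_simple_equation("bernoulli_cosh", {"a2": a2, "ap2": ap2, "p": p})
    return {"mu": sp.simplify(mu), "nu": sp.simplify(nu), "simple_equation": se, "u": u}
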