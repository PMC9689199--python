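"""Symbolic kernel: expression grammar, equation specs, traveling-wave
substitution, derivative reduction through an auxiliary ODE, and coefficient
collection.

Expressions are plain :class:`sympy.Expr` trees restricted to a documented
ASCII grammar (see ``docs/methods.md``): rational constants, named symbols,
a whitelist of function applications, the arithmetic operators ``+ - * / ^``
and derivative markers.  All numeric literals are kept as exact
:class:`sympy.Rational` objects; floating-point numbers never enter stored
expressions, so residual computations remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import sympy as sp
from sympy.parsing.sympy_parser import (
    auto_number,
    auto_symbol,
    convert_xor,
    parse_expr,
    rationalize,
)

__all__ = [
    "GRAMMAR_FUNCTIONS",
    "ExpressionError",
    "parse_expression",
    "serialize_expression",
    "EquationSpec",
    "PolynomialForm",
    "AlgebraicSystem",
    "substitute_traveling_wave",
    "reduce_derivatives",
    "collect_coefficients",
]


class ExpressionError(ValueError):
    """Raised for grammar violations, unknown functions, or malformed specs."""


class sn(sp.Function):
    """Jacobi elliptic sn(u, m); numeric evaluation through mpmath."""

    nargs = (2,)

    def _eval_evalf(self, prec):
        import mpmath

        with mpmath.workprec(prec):
            u, m = [sp.Float(a, prec)._to_mpmath(prec) for a in self.args]
            return sp.Expr._from_mpmath(mpmath.ellipfun("sn", u, m=m), prec)


class cn(sp.Function):
    """Jacobi elliptic cn(u, m)."""

    nargs = (2,)

    def _eval_evalf(self, prec):
        import mpmath

        with mpmath.workprec(prec):
            u, m = [sp.Float(a, prec)._to_mpmath(prec) for a in self.args]
            return sp.Expr._from_mpmath(mpmath.ellipfun("cn", u, m=m), prec)


class dn(sp.Function):
    """Jacobi elliptic dn(u, m)."""

    nargs = (2,)

    def _eval_evalf(self, prec):
        import mpmath

        with mpmath.workprec(prec):
            u, m = [sp.Float(a, prec)._to_mpmath(prec) for a in self.args]
            return sp.Expr._from_mpmath(mpmath.ellipfun("dn", u, m=m), prec)


class wp(sp.Function):
    """Weierstrass elliptic function ℘(z; g2, g3) (symbolic placeholder)."""

    nargs = (3,)


#: Function names admitted by the expression grammar.
GRAMMAR_FUNCTIONS: dict[str, sp.FunctionClass] = {
    "exp": sp.exp,
    "log": sp.log,
    "ln": sp.log,
    "sqrt": sp.sqrt,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "cot": sp.cot,
    "sinh": sp.sinh,
    "cosh": sp.cosh,
    "tanh": sp.tanh,
    "coth": sp.coth,
    "sech": sp.sech,
    "csch": sp.csch,
    "arctan": sp.atan,
    "atan": sp.atan,
    "arccot": sp.acot,
    "acot": sp.acot,
    "artanh": sp.atanh,
    "atanh": sp.atanh,
    "arcoth": sp.acoth,
    "acoth": sp.acoth,
    "sn": sn,
    "cn": cn,
    "dn": dn,
    "wp": wp,
    "Abs": sp.Abs,
    "conjugate": sp.conjugate,
    "Derivative": sp.Derivative,
    "diff": sp.Derivative,
}

_PARSE_TRANSFORMS = (auto_symbol, auto_number, rationalize, convert_xor)

# restricted global namespace: names like "gamma" or "beta" are plain symbols,
# never sympy special functions; I/pi/E keep their usual meaning
_PARSE_GLOBALS = {
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    "Symbol": sp.Symbol,
    "Function": sp.Function,
    "I": sp.I,
    "pi": sp.pi,
    "E": sp.E,
}


def _strip_comments(text: str) -> str:
    return "\n".join(line.split(";", 1)[0] for line in text.splitlines())


def parse_expression(text: str, functions: Mapping[str, sp.Function] | None = None) -> sp.Expr:
    """Parse a grammar string into an exact sympy expression.

    ``^`` denotes powers, ``;`` starts a comment, function application uses
    call syntax.  Unknown function names raise :class:`ExpressionError`;
    decimal literals are converted to exact rationals.
    """
    src = _strip_comments(text).strip()
    if not src:
        raise ExpressionError("empty expression")
    local: dict[str, object] = dict(GRAMMAR_FUNCTIONS)
    if functions:
        local.update(functions)
    try:
        expr = parse_expr(
            src,
            local_dict=local,
            global_dict=dict(_PARSE_GLOBALS),
            transformations=_PARSE_TRANSFORMS,
            evaluate=True,
        )
    except (SyntaxError, TypeError, sp.SympifyError) as exc:
        raise ExpressionError(f"syntax error in {text!r}: {exc}") from exc
    declared = set(local) | ({f.__name__ for f in (functions or {}).values() if callable(f)})
    for f in expr.atoms(sp.Function):
        name = type(f).__name__
        if name not in declared:
            raise ExpressionError(f"unknown function {name!r}")
    if expr.atoms(sp.Float):
        expr = sp.nsimplify(expr, rational=True)
    return expr


def serialize_expression(expr: sp.Expr) -> str:
    """Serialize an expression to the grammar; ``parse ∘ serialize`` is the
    identity on expression trees."""
    return sp.sstr(expr).replace("**", "^")


@dataclass(frozen=True)
class EquationSpec:
    """An equation ``lhs = 0`` with a declared unknown function, ordered
    independent variables, and free parameters.

    ``conditions`` holds inequality constraints on the parameters (e.g.
    positivity of a dispersion coefficient) carried along the pipeline.
    """

    lhs: sp.Expr
    unknown: str
    independent_vars: tuple[str, ...]
    parameters: frozenset[str] = frozenset()
    conditions: tuple[sp.Expr, ...] = ()

    def __post_init__(self) -> None:
        allowed = set(self.independent_vars) | set(self.parameters)
        for s in self.lhs.free_symbols:
            if s.name not in allowed and s.name != self.unknown:
                raise ExpressionError(
                    f"symbol {s.name!r} in equation is neither the unknown, an "
                    f"independent variable, nor a declared parameter"
                )

    @property
    def unknown_func(self) -> sp.Function:
        return sp.Function(self.unknown)

    @property
    def var_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(v) for v in self.independent_vars)

    @property
    def applied_unknown(self) -> sp.Expr:
        return self.unknown_func(*self.var_symbols)

    @classmethod
    def from_text(
        cls,
        lhs: str,
        unknown: str,
        independent_vars: Sequence[str],
        parameters: Iterable[str] = (),
        conditions: Iterable[str] = (),
    ) -> "EquationSpec":
        u = sp.Function(unknown)
        local = {unknown: u}
        expr = parse_expression(lhs, functions=local)
        conds = tuple(parse_expression(c) for c in conditions)
        return cls(expr, unknown, tuple(independent_vars), frozenset(parameters), conds)

    def to_dict(self) -> dict:
        return {
            "lhs": serialize_expression(self.lhs),
            "unknown": self.unknown,
            "vars": list(self.independent_vars),
            "params": sorted(self.parameters),
            "conditions": [serialize_expression(c) for c in self.conditions],
        }


def substitute_traveling_wave(
    eq: EquationSpec,
    wave_map: Mapping[str, sp.Expr | str | int],
    xi_name: str = "xi",
) -> EquationSpec:
    """Rewrite a PDE in the traveling-wave coordinate ξ = Σ cᵥ·v.

    ``wave_map`` assigns each independent variable its coefficient in ξ, e.g.
    ``{"x": 1, "t": -v}`` for ξ = x − vt or ``{"x": mu, "t": nu}``.  Every
    partial derivative ∂ⁿ⁺ᵐu/∂xⁿ∂tᵐ becomes cₓⁿ·cₜᵐ·dⁿ⁺ᵐU/dξⁿ⁺ᵐ by the chain
    rule.
    """
    coeffs: dict[str, sp.Expr] = {}
    for v, c in wave_map.items():
        if v not in eq.independent_vars:
            raise ExpressionError(f"unknown independent variable {v!r} in wave map")
        coeffs[v] = parse_expression(c) if isinstance(c, str) else sp.sympify(c)
    xi = sp.Symbol(xi_name)
    U = sp.Function(eq.unknown)
    u_applied = eq.applied_unknown

    def rewrite_derivative(d: sp.Derivative) -> sp.Expr:
        if d.expr != u_applied:
            return d
        factor = sp.Integer(1)
        total = 0
        for var, order in d.variable_count:
            name = var.name
            if name not in coeffs:
                raise ExpressionError(f"variable {name!r} missing from wave map")
            factor *= coeffs[name] ** order
            total += int(order)
        return factor * sp.Derivative(U(xi), (xi, total))

    lhs = eq.lhs.replace(
        lambda e: isinstance(e, sp.Derivative) and e.expr == u_applied,
        rewrite_derivative,
    )
    lhs = lhs.subs(u_applied, U(xi))
    params = set(eq.parameters)
    for c in coeffs.values():
        params |= {s.name for s in c.free_symbols}
    return EquationSpec(lhs.doit(), eq.unknown, (xi_name,), frozenset(params), eq.conditions)


@dataclass
class PolynomialForm:
    """A polynomial representation over powers of V (and optionally V′ to the
    first power) with expression coefficients.

    Keys are ``(i, j)`` with ``V^i · (V')^j`` and ``j ∈ {0, 1}``.  Negative
    ``i`` is admitted only in Laurent mode.
    """

    gen: sp.Symbol
    dgen: sp.Symbol | None
    coeffs: dict[tuple[int, int], sp.Expr]
    laurent: bool = False

    def __post_init__(self) -> None:
        for (i, j), c in self.coeffs.items():
            if j not in (0, 1):
                raise ExpressionError("V' exponent must be 0 or 1 in a PolynomialForm")
            if i < 0 and not self.laurent:
                raise ExpressionError("negative powers require Laurent mode")

    def expand(self) -> sp.Expr:
        d = self.dgen if self.dgen is not None else sp.Integer(1)
        return sp.expand(
            sum(c * self.gen**i * d**j for (i, j), c in self.coeffs.items())
        )

    def __iter__(self):
        return iter(sorted(self.coeffs.items(), key=lambda kv: (-(kv[0][0] + kv[0][1]), -kv[0][1])))


@dataclass
class AlgebraicSystem:
    """An ordered system of algebraic relations (each Expression = 0) in the
    ansatz coefficients and equation parameters."""

    relations: tuple[sp.Expr, ...]
    unknowns: tuple[sp.Symbol, ...] = ()
    parameters: tuple[sp.Symbol, ...] = ()

    def __len__(self) -> int:
        return len(self.relations)

    def subs(self, assignment: Mapping[sp.Symbol, sp.Expr]) -> "AlgebraicSystem":
        return AlgebraicSystem(
            tuple(sp.simplify(r.subs(assignment)) for r in self.relations),
            tuple(u for u in self.unknowns if u not in assignment),
            self.parameters,
        )

    def is_satisfied_by(self, assignment: Mapping[sp.Symbol, sp.Expr]) -> bool:
        for r in self.relations:
            val = sp.simplify(sp.together(r.subs(assignment)))
            if sp.simplify(sp.radsimp(val)) != 0 and sp.factor(val) != 0:
                return False
        return True


def _first_order_derivative_table(rhs: sp.Expr, V: sp.Symbol, max_order: int) -> list[sp.Expr]:
    """dⁿV/dξⁿ as polynomials in V for V' = rhs(V)."""
    table = [V, sp.expand(rhs)]
    for _ in range(2, max_order + 1):
        table.append(sp.expand(sp.diff(table[-1], V) * rhs))
    return table


def _squared_family_derivative_table(
    rhs: sp.Expr, V: sp.Symbol, W: sp.Symbol, max_order: int
) -> list[sp.Expr]:
    """dⁿV/dξⁿ in terms of V and W = V' for (V')² = rhs(V).

    Differentiation rule: d/dξ E(V, W) = E_V·W + E_W·(rhs'(V)/2); even powers
    of W are rewritten through the defining polynomial so W never exceeds
    power one.
    """
    w2 = sp.expand(rhs)
    wprime = sp.expand(sp.diff(rhs, V) / 2)

    def reduce_w(e: sp.Expr) -> sp.Expr:
        e = sp.expand(e)
        p = sp.Poly(e, W)
        out = sp.Integer(0)
        for (k,), c in p.terms():
            q, r = divmod(k, 2)
            out += c * w2**q * W**r
        return sp.expand(out)

    def d_dxi(e: sp.Expr) -> sp.Expr:
        return reduce_w(sp.diff(e, V) * W + sp.diff(e, W) * wprime)

    table = [V, W]
    for _ in range(2, max_order + 1):
        table.append(d_dxi(table[-1]))
    return table


def reduce_derivatives(
    expr: sp.Expr,
    se,
    xi: sp.Symbol | None = None,
    laurent: bool = False,
) -> PolynomialForm:
    """Eliminate ξ-derivatives of the unknown using a simple equation.

    ``expr`` must be polynomial (Laurent-polynomial in Laurent mode) in the
    unknown function of ξ and its derivatives.  For a first-order simple
    equation V' = P(V) the result is a polynomial in V alone; for the
    squared-derivative family (V')² = Q(V) the basis is powers of V plus
    V-powers times a single factor of V'.
    """
    from .simple_equations import SimpleEquation  # local import, no cycle at import time

    if not isinstance(se, SimpleEquation):
        raise TypeError("se must be a SimpleEquation")
    xi = xi if xi is not None else sp.Symbol("xi")
    V = sp.Symbol("_V")
    W = sp.Symbol("_Vp")

    # locate the unknown function applications of one argument
    funcs = {f for f in expr.atoms(sp.core.function.AppliedUndef) if len(f.args) == 1}
    if len(funcs) > 1:
        raise ExpressionError(f"expected a single unknown function, found {funcs}")
    max_order = 0
    for d in expr.atoms(sp.Derivative):
        if isinstance(d.expr, sp.core.function.AppliedUndef):
            max_order = max(max_order, sum(int(o) for _, o in d.variable_count))

    rhs = se.derivative_rule(V)
    if se.is_squared_family:
        table = _squared_family_derivative_table(rhs, V, W, max_order)
    else:
        table = _first_order_derivative_table(rhs, V, max_order)

    def replace_node(e: sp.Expr) -> sp.Expr:
        if isinstance(e, sp.Derivative) and isinstance(e.expr, sp.core.function.AppliedUndef):
            n = sum(int(o) for _, o in e.variable_count)
            if n >= len(table):
                raise ExpressionError("derivative order exceeds reduction table")
            return table[n]
        return e

    work = expr.replace(
        lambda e: isinstance(e, sp.Derivative) and isinstance(e.expr, sp.core.function.AppliedUndef),
        replace_node,
    )
    for f in funcs:
        work = work.subs(f, V)
    if work.has(xi):
        raise ExpressionError("residual dependence on the wave coordinate after reduction")
    work = sp.expand(work)

    # final W-power clean-up (products of first-order derivatives)
    if se.is_squared_family and work.has(W):
        w2 = sp.expand(rhs)
        p = sp.Poly(work, W)
        work = sp.expand(
            sum(c * w2 ** (k // 2) * W ** (k % 2) for (k,), c in p.terms())
        )
    elif work.has(W):
        raise ExpressionError("simple equation cannot eliminate a first derivative")

    coeffs: dict[tuple[int, int], sp.Expr] = {}
    gens = (V, W) if work.has(W) else (V,)
    if laurent:
        # collect over Laurent powers by clearing the minimal V power first
        pw = sp.Wild("pw", exclude=[V])
        shifted = sp.expand(sp.together(work))
        num, den = sp.fraction(shifted)
        dpoly = sp.Poly(den, V)
        if len(dpoly.monoms()) != 1:
            raise ExpressionError("Laurent reduction requires a monomial denominator in V")
        shift = dpoly.monoms()[0][0]
        dc = dpoly.coeffs()[0]
        work_num = sp.expand(num / dc)
        p = sp.Poly(work_num, *gens)
        for mon, c in zip(p.monoms(), p.coeffs()):
            i = mon[0] - shift
            j = mon[1] if len(mon) > 1 else 0
            coeffs[(int(i), int(j))] = sp.simplify(c)
    else:
        p = sp.Poly(work, *gens)
        for mon, c in zip(p.monoms(), p.coeffs()):
            j = mon[1] if len(mon) > 1 else 0
            coeffs[(int(mon[0]), int(j))] = c
    pf = PolynomialForm(V, W if any(j for _, j in coeffs) else None, coeffs, laurent=laurent)
    return pf


def collect_coefficients(pf: PolynomialForm) -> AlgebraicSystem:
    """One relation per basis element with a nonzero coefficient, ordered by
    descending basis degree (then V′ power) so system layout is deterministic."""
    relations = []
    forbidden = {pf.gen} | ({pf.dgen} if pf.dgen is not None else set())
    for (i, j), c in pf:
        c = sp.expand(c)
        if c == 0:
            continue
        if c.free_symbols & forbidden or c.has(sp.Symbol("xi")):
            raise ExpressionError(f"coefficient of basis ({i},{j}) still depends on V or ξ")
        relations.append(c)
    symbols = sorted({s for r in relations for s in r.free_symbols}, key=lambda s: s.name)
    return AlgebraicSystem(tuple(relations), tuple(symbols))
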