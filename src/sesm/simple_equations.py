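"""Catalog of simple (auxiliary) ODEs with closed-form solution branches.

A *simple equation* is a first-order ODE with known exact solutions that the
solver pipeline uses as a building block: the solution of the target equation
is assembled as a polynomial (or composite function) of the simple equation's
solution.  Shipped families:

``exponential``      V′ = a·V
``bernoulli``        V′ = a·V + b·V^k          (k integer > 1)
``riccati``          V′ = a·V² + b·V + c
``extended_tanh``    V′ = c̄² − ā²·V²
``polynomial``       V′ = Σ γ_α V^α            (generic first-order)
``squared_poly``     (dᵏV/dξᵏ)ˡ = Σ a_j V^j    (V-function family; derivative
                     reduction implemented for k=1, l ∈ {1, 2})

For k=1, l=2 the family defines a special function containing hyperbolic,
trigonometric, Weierstrass and Jacobi degenerations; closed-form branches are
provided for the named special cases (pure exponential and the
``Ω·cosh^{−2/p}`` soliton profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy as sp

from .expressions import ExpressionError, parse_expression, serialize_expression

__all__ = [
    "SimpleEquation",
    "SolutionBranch",
    "make_simple_equation",
    "solution_branches",
    "evaluate_branch",
]

_FAMILIES = {
    "exponential",
    "bernoulli",
    "riccati",
    "extended_tanh",
    "polynomial",
    "squared_poly",
    "bernoulli_cosh",
}


def _sym(v):
    if isinstance(v, str):
        return parse_expression(v)
    return sp.sympify(v, rational=True)


@dataclass(frozen=True)
class SimpleEquation:
    """An auxiliary ODE family instance with fixed (possibly symbolic)
    parameters."""

    family: str
    params: tuple[tuple[str, sp.Expr], ...]
    unknown: str = "V"
    var: str = "xi"

    @property
    def p(self) -> dict[str, sp.Expr]:
        return dict(self.params)

    @property
    def is_squared_family(self) -> bool:
        if self.family == "bernoulli_cosh":
            return True
        if self.family == "squared_poly":
            return int(self.p["l"]) == 2
        return False

    @property
    def order(self) -> int:
        return int(self.p.get("k_order", 1)) if self.family == "squared_poly" else 1

    @property
    def degree(self) -> int:
        """Highest power of V on the right-hand side of the defining ODE."""
        rhs = self.derivative_rule(sp.Symbol("_V"))
        return sp.Poly(rhs, sp.Symbol("_V")).degree()

    def derivative_rule(self, V: sp.Symbol) -> sp.Expr:
        """RHS of V′ = rhs(V) (first-order families) or of (V′)² = rhs(V)
        (squared-derivative families)."""
        p = self.p
        if self.family == "exponential":
            return p["a"] * V
        if self.family == "bernoulli":
            return p["a"] * V + p["b"] * V ** int(p["k"])
        if self.family == "riccati":
            return p["a"] * V**2 + p["b"] * V + p["c"]
        if self.family == "extended_tanh":
            return p["cbar"] ** 2 - p["abar"] ** 2 * V**2
        if self.family == "polynomial":
            return sum(c * V**j for j, c in enumerate(p["coeffs"]))
        if self.family == "bernoulli_cosh":
            pp = int(p["p"])
            return p["a2"] * V**2 + p["ap2"] * V ** (pp + 2)
        if self.family == "squared_poly":
            if int(p["k_order"]) != 1 or int(p["l"]) not in (1, 2):
                raise ExpressionError(
                    "derivative reduction implemented only for first-order "
                    "simple equations (k=1, l in {1,2})"
                )
            return sum(c * V**j for j, c in enumerate(p["coeffs"]))
        raise ExpressionError(f"unknown family {self.family!r}")

    def defining_expression(self) -> sp.Expr:
        """LHS − RHS of the defining ODE applied to unknown(var)."""
        xi = sp.Symbol(self.var)
        Vf = sp.Function(self.unknown)(xi)
        rhs = self.derivative_rule(sp.Symbol("_V")).subs(sp.Symbol("_V"), Vf)
        if self.is_squared_family:
            return sp.Derivative(Vf, xi) ** 2 - rhs
        return sp.Derivative(Vf, xi) - rhs

    def residual_of(self, closed_form: sp.Expr) -> sp.Expr:
        """Substitute a candidate closed form V(ξ) into the defining ODE."""
        xi = sp.Symbol(self.var)
        rhs = self.derivative_rule(sp.Symbol("_V")).subs(sp.Symbol("_V"), closed_form)
        if self.is_squared_family:
            return sp.diff(closed_form, xi) ** 2 - rhs
        return sp.diff(closed_form, xi) - rhs


@dataclass(frozen=True)
class SolutionBranch:
    """A verified closed-form solution branch of a simple equation, with the
    parameter conditions under which it is real and nonsingular."""

    equation: SimpleEquation
    expr: sp.Expr
    conditions: tuple[sp.Expr, ...] = ()
    singularity: str = ""

    def residual(self) -> sp.Expr:
        return self.equation.residual_of(self.expr)

    def is_verified(self) -> bool:
        r = self.residual()
        r = sp.simplify(sp.powsimp(sp.radsimp(r), force=True))
        if r == 0:
            return True
        return sp.simplify(sp.factor(sp.cancel(r))) == 0


def make_simple_equation(
    family: str,
    params: Mapping[str, object] | None = None,
    unknown: str = "V",
    var: str = "xi",
) -> SimpleEquation:
    """Construct a simple-equation instance, validating family arity."""
    if family not in _FAMILIES:
        raise ExpressionError(f"unknown simple-equation family {family!r}")
    params = dict(params or {})
    norm: dict[str, sp.Expr] = {}
    if family == "exponential":
        norm["a"] = _sym(params.get("a", 1))
    elif family == "bernoulli":
        for key in ("a", "b", "k"):
            if key not in params:
                raise ExpressionError(f"bernoulli requires parameter {key!r}")
        k = int(params["k"])
        if k <= 1:
            raise ExpressionError("bernoulli exponent k must be an integer > 1")
        norm.update(a=_sym(params["a"]), b=_sym(params["b"]), k=sp.Integer(k))
    elif family == "riccati":
        for key in ("a", "b", "c"):
            if key not in params:
                raise ExpressionError(f"riccati requires parameter {key!r}")
            norm[key] = _sym(params[key])
    elif family == "extended_tanh":
        for key in ("abar", "cbar"):
            if key not in params:
                raise ExpressionError(f"extended_tanh requires parameter {key!r}")
            norm[key] = _sym(params[key])
    elif family == "polynomial":
        coeffs = tuple(_sym(c) for c in params["coeffs"])
        if not coeffs:
            raise ExpressionError("polynomial family needs a coefficient vector")
        norm["coeffs"] = coeffs
    elif family == "bernoulli_cosh":
        for key in ("a2", "ap2", "p"):
            if key not in params:
                raise ExpressionError(f"bernoulli_cosh requires parameter {key!r}")
        norm.update(a2=_sym(params["a2"]), ap2=_sym(params["ap2"]), p=sp.Integer(int(params["p"])))
    elif family == "squared_poly":
        k_order = int(params.get("k", params.get("k_order", 1)))
        l = int(params["l"])
        coeffs = tuple(_sym(c) for c in params["coeffs"])
        if int(params.get("m", len(coeffs) - 1)) != len(coeffs) - 1:
            raise ExpressionError("coefficient vector length must be m+1")
        norm.update(k_order=sp.Integer(k_order), l=sp.Integer(l), coeffs=coeffs)

    def freeze(d):
        return tuple(
            (k, v if not isinstance(v, tuple) else v) for k, v in sorted(d.items())
        )

    return SimpleEquation(family, freeze(norm), unknown, var)


def solution_branches(se: SimpleEquation, xi0: sp.Symbol | None = None) -> list[SolutionBranch]:
    """Closed-form solution branches with validity conditions.

    Every returned branch substitutes into the defining ODE to a symbolically
    zero residual under its conditions (property-tested).  Families without a
    named closed form return an empty list.
    """
    xi = sp.Symbol(se.var)
    xi0 = xi0 if xi0 is not None else sp.Symbol("xi0")
    p = se.p
    out: list[SolutionBranch] = []
    if se.family == "exponential":
        out.append(SolutionBranch(se, sp.exp(p["a"] * (xi + xi0))))
    elif se.family == "bernoulli":
        a, b, k = p["a"], p["b"], int(p["k"])
        E = sp.exp(a * (k - 1) * (xi + xi0))
        out.append(
            SolutionBranch(
                se,
                (a * E / (1 - b * E)) ** sp.Rational(1, k - 1),
                (sp.Symbol("b") < 0, sp.Symbol("a") > 0) if a == sp.Symbol("a") else (),
                singularity="pole where b·exp(a(k−1)(ξ+ξ₀)) = 1",
            )
        )
        out.append(
            SolutionBranch(
                se,
                (-a * E / (1 + b * E)) ** sp.Rational(1, k - 1),
                (sp.Symbol("b") > 0, sp.Symbol("a") < 0) if a == sp.Symbol("a") else (),
                singularity="pole where b·exp(a(k−1)(ξ+ξ₀)) = −1",
            )
        )
    elif se.family == "riccati":
        a, b, c = p["a"], p["b"], p["c"]
        theta = sp.sqrt(b**2 - 4 * a * c)
        out.append(
            SolutionBranch(
                se,
                -b / (2 * a) - theta / (2 * a) * sp.tanh(theta * (xi + xi0) / 2),
                (b**2 - 4 * a * c > 0,),
            )
        )
    elif se.family == "extended_tanh":
        ab, cb = p["abar"], p["cbar"]
        out.append(
            SolutionBranch(
                se,
                cb / ab * sp.tanh(ab * cb * (xi + xi0)),
                (sp.Symbol("abar") ** 2 * sp.Symbol("V") ** 2 < sp.Symbol("cbar") ** 2,),
            )
        )
    elif se.family == "bernoulli_cosh":
        a2, ap2, pp = p["a2"], p["ap2"], int(p["p"])
        # g = Ω·cosh^{−2/p}(ω(ξ+ξ₀));  ω = (p/2)√a2,  Ωᵖ = −a2/ap2
        omega = pp * sp.sqrt(a2) / 2
        Omega = (-a2 / ap2) ** sp.Rational(1, pp)
        out.append(
            SolutionBranch(
                se,
                Omega * sp.cosh(omega * (xi + xi0)) ** sp.Rational(-2, pp),
                (a2 > 0,),
            )
        )
    elif se.family == "squared_poly" and int(p.get("l", 0)) == 2 and int(p["k_order"]) == 1:
        coeffs = p["coeffs"]
        nz = [j for j, c in enumerate(coeffs) if c != 0]
        if nz == [2]:
            # (V′)² = a₂V² → pure exponentials
            for s in (1, -1):
                out.append(SolutionBranch(se, sp.exp(s * sp.sqrt(coeffs[2]) * (xi + xi0))))
        elif len(nz) == 2 and 2 in nz:
            j = next(i for i in nz if i != 2)
            if j > 2:
                pp = j - 2
                sub = make_simple_equation(
                    "bernoulli_cosh", {"a2": coeffs[2], "ap2": coeffs[j], "p": pp},
                    unknown=se.unknown, var=se.var,
                )
                for br in solution_branches(sub, xi0):
                    out.append(SolutionBranch(se, br.expr, br.conditions, br.singularity))
    return out


def evaluate_branch(
    branch: SolutionBranch,
    points: Sequence[object],
    digits: int = 50,
    pole_magnitude: float = 1e40,
) -> list[sp.Float]:
    """Evaluate a branch at the given ξ points to ``digits`` significant
    digits, refusing points at or near a pole."""
    xi = sp.Symbol(branch.equation.var)
    values = []
    for pt in points:
        val = branch.expr.subs(xi, sp.nsimplify(pt, rational=True)).evalf(digits)
        if not val.is_real and val.has(sp.I):
            val_c = sp.re(val) if abs(sp.im(val)) < sp.Float(10) ** (-digits + 5) else None
            if val_c is None:
                raise ExpressionError(f"complex value at ξ={pt}; branch conditions violated")
            val = val_c
        if not val.is_number or abs(val) > pole_magnitude:
            raise ExpressionError(f"evaluation at ξ={pt} is at or near a pole")
        values.append(val)
    return values
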