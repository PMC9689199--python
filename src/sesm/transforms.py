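"""Step-1 transformations: convert non-polynomial nonlinearities to
polynomial ones.

An equation containing a transcendental nonlinearity N(u) — an exponential,
a (hyperbolic) trigonometric function, or an integer power of one — can be
rewritten with a substitution u = T(F) so that N and every derivative of u
become rational in F and its derivatives.  Multiplying by a minimal clearing
factor (a power of F, 1+F², or 1−F²) then leaves an equation polynomial in
F.  The clearing factor is reported so that solution validity conditions can
exclude its zero set; inverse maps use principal branches of arctan/artanh.

The case catalog ships as ``data/transform_catalog.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import sympy as sp

from .expressions import EquationSpec, ExpressionError, parse_expression

__all__ = ["TransformCase", "load_catalog", "match_transform", "apply_transform"]

_PATTERN_HEADS = {
    "exp": (sp.exp,),
    "sin": (sp.sin,),
    "cos": (sp.cos,),
    "tan": (sp.tan,),
    "cot": (sp.cot,),
    "sinh": (sp.sinh,),
    "cosh": (sp.cosh,),
    "tanh": (sp.tanh,),
    "coth": (sp.coth,),
    "sin_or_cos_of_multiple": (sp.sin, sp.cos),
}


@dataclass(frozen=True)
class TransformCase:
    """One catalog entry: a nonlinearity pattern with its forward map
    u = T(F) and inverse F = T⁻¹(u)."""

    id: int
    pattern: str
    forward: sp.Expr  # in terms of Symbol('F')
    inverse: sp.Expr  # in terms of Symbol('u')

    def forward_map(self, F_expr: sp.Expr) -> sp.Expr:
        return self.forward.subs(sp.Symbol("F"), F_expr)

    def inverse_map(self, u_expr: sp.Expr) -> sp.Expr:
        return self.inverse.subs(sp.Symbol("u"), u_expr)

    def pattern_applied_to(self, u: sp.Expr) -> sp.Expr:
        """Representative N(u) for this case (first head for dual patterns)."""
        return _PATTERN_HEADS[self.pattern][0](u)


def load_catalog() -> list[TransformCase]:
    raw = json.loads(
        resources.files("sesm.data").joinpath("transform_catalog.json").read_text()
    )
    out = []
    for c in raw["cases"]:
        out.append(
            TransformCase(
                c["id"],
                c["pattern"],
                parse_expression(c["forward"]),
                parse_expression(c["inverse"]),
            )
        )
    return out


def _nonlinearity_heads(eq: EquationSpec) -> dict[type, list[sp.Expr]]:
    """Transcendental function applications whose argument contains the
    unknown, keyed by function head."""
    u = eq.applied_unknown
    found: dict[type, list[sp.Expr]] = {}
    for node in sp.preorder_traversal(eq.lhs):
        if isinstance(node, sp.Function) and not isinstance(
            node, sp.core.function.AppliedUndef
        ):
            if any(a.has(u) for a in node.args):
                found.setdefault(type(node), []).append(node)
    return found


def match_transform(eq: EquationSpec, catalog: list[TransformCase] | None = None) -> list[TransformCase]:
    """All catalog cases whose pattern occurs in the equation.

    A purely polynomial equation returns the empty list.  Overlapping cases
    (plain sin/cos versus sin/cos of a multiple of u) are both returned; the
    caller chooses.
    """
    catalog = catalog if catalog is not None else load_catalog()
    heads = _nonlinearity_heads(eq)
    u = eq.applied_unknown
    out = []
    for case in catalog:
        for head in _PATTERN_HEADS[case.pattern]:
            nodes = heads.get(head, [])
            if not nodes:
                continue
            if case.pattern == "sin_or_cos_of_multiple":
                # argument m*u with m != 1 (or any non-trivial multiple)
                if any(sp.simplify(n.args[0] / u).is_number for n in nodes):
                    out.append(case)
                    break
            else:
                if any(sp.simplify(n.args[0] - u) == 0 for n in nodes):
                    out.append(case)
                    break
    return out


def _is_polynomial_in_F(expr: sp.Expr, F: sp.Expr) -> bool:
    """True if expr is polynomial in F and its derivatives."""
    gens = {F} | {d for d in expr.atoms(sp.Derivative) if d.expr == F}
    try:
        sp.Poly(sp.expand(expr), *sorted(gens, key=sp.default_sort_key))
        return True
    except (sp.PolynomialError, sp.GeneratorsError):
        return False


def apply_transform(
    eq: EquationSpec, case: TransformCase, new_unknown: str = "F"
) -> tuple[EquationSpec, sp.Expr]:
    """Substitute u = T(F) and clear the common denominator.

    Returns the polynomial equation in F together with the clearing factor
    that multiplied the equation (its zero set must be excluded from any
    solution's validity domain).  Raises if a non-polynomial term survives
    — the transformation hypotheses are then violated for this equation.
    """
    u = eq.applied_unknown
    F = sp.Function(new_unknown)(*eq.var_symbols)
    Tf = case.forward_map(F)
    lhs = eq.lhs.replace(
        lambda e: isinstance(e, sp.Derivative) and e.expr == u,
        lambda d: sp.Derivative(Tf, *d.variable_count),
    )
    lhs = lhs.subs(u, Tf).doit()
    lhs = sp.expand_trig(lhs)
    lhs = sp.radsimp(sp.cancel(sp.together(sp.expand(lhs))))
    num, den = sp.fraction(sp.together(lhs))
    num = sp.expand(num)
    if not _is_polynomial_in_F(num, F):
        raise ExpressionError(
            "transformation left a non-polynomial term; the nonlinearity is "
            "not of the catalogued kind"
        )
    params = set(eq.parameters)
    out = EquationSpec(num, new_unknown, eq.independent_vars, frozenset(params), eq.conditions)
    return out, sp.factor(den)
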