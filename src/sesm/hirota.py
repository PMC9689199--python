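"""Hirota bilinear bridge: D-operators, the bilinear KdV form, the
order-by-order expansion chain, and explicit 1/2/3-soliton construction.

The KdV equation u_t + 6uu_x + u_xxx = 0 becomes bilinear,
(D_x D_t + D_x⁴)(f·f) = 0, under u = 2∂²(ln f)/∂x².  Writing
f = 1 + εf₁ + ε²f₂ + ε³f₃ + … yields a chain of linear equations, one per
order of ε, solved by exponentials exp(ηᵢ) with ηᵢ = λᵢx + ωᵢt + σᵢ and the
dispersion relation ωᵢ = −λᵢ³.  The chain truncates for N ≤ 3 solitons with
interaction coefficients a_ij = (λᵢ−λⱼ)²/(λᵢ+λⱼ)² and b₁₂₃ = a₁₂a₁₃a₂₃.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import sympy as sp

from .expressions import ExpressionError

__all__ = [
    "d_operator",
    "SolitonSet",
    "multisoliton_f",
    "f_to_u",
    "verify_bilinear_chain",
    "kdv_residual",
]

_x, _t = sp.symbols("x t")


def d_operator(
    m: int,
    n: int,
    a: sp.Expr,
    b: sp.Expr,
    x: sp.Symbol = _x,
    t: sp.Symbol = _t,
) -> sp.Expr:
    """Hirota bilinear operator D_xᵐ D_tⁿ (a·b).

    Expanded as the double sum
    Σⱼ Σᵢ (−1)^{m+n−j−i} C(m,j) C(n,i) ∂ₜⁱ∂ₓʲa · ∂ₜ^{n−i}∂ₓ^{m−j}b.
    """
    if m < 0 or n < 0:
        raise ExpressionError("operator orders must be non-negative")
    total = sp.Integer(0)
    for j in range(m + 1):
        for i in range(n + 1):
            total += (
                sp.Integer(-1) ** (m + n - j - i)
                * sp.binomial(m, j)
                * sp.binomial(n, i)
                * sp.diff(a, t, i, x, j)
                * sp.diff(b, t, n - i, x, m - j)
            )
    return sp.expand(total)


@dataclass(frozen=True)
class SolitonSet:
    """Wavenumbers, phases, and derived interaction data for N ≤ 3 solitons."""

    lambdas: tuple[sp.Expr, ...]
    sigmas: tuple[sp.Expr, ...]

    def __post_init__(self) -> None:
        N = len(self.lambdas)
        if not 1 <= N <= 3:
            raise ExpressionError("1 to 3 solitons supported")
        if len(self.sigmas) != N:
            raise ExpressionError("one phase per wavenumber required")
        for i, j in combinations(range(N), 2):
            if sp.simplify(self.lambdas[i] - self.lambdas[j]) == 0:
                raise ExpressionError("wavenumbers must be distinct")
            if sp.simplify(self.lambdas[i] + self.lambdas[j]) == 0:
                raise ExpressionError("colliding wavenumbers (λi + λj = 0)")

    @property
    def n(self) -> int:
        return len(self.lambdas)

    @property
    def omegas(self) -> tuple[sp.Expr, ...]:
        return tuple(-l**3 for l in self.lambdas)

    def eta(self, i: int, x: sp.Symbol = _x, t: sp.Symbol = _t) -> sp.Expr:
        return self.lambdas[i] * x + self.omegas[i] * t + self.sigmas[i]

    def a_ij(self, i: int, j: int) -> sp.Expr:
        li, lj = self.lambdas[i], self.lambdas[j]
        return (li - lj) ** 2 / (li + lj) ** 2

    @property
    def b123(self) -> sp.Expr:
        if self.n != 3:
            raise ExpressionError("b123 requires three solitons")
        return self.a_ij(0, 1) * self.a_ij(0, 2) * self.a_ij(1, 2)

    def f_components(self, x: sp.Symbol = _x, t: sp.Symbol = _t):
        """(f₁, f₂, f₃) of the expansion, with ε set to 1 (absorbed into the
        phases)."""
        f1 = sum(sp.exp(self.eta(i, x, t)) for i in range(self.n))
        f2 = sum(
            self.a_ij(i, j) * sp.exp(self.eta(i, x, t) + self.eta(j, x, t))
            for i, j in combinations(range(self.n), 2)
        )
        f3 = (
            self.b123 * sp.exp(sum(self.eta(i, x, t) for i in range(3)))
            if self.n == 3
            else sp.Integer(0)
        )
        return f1, f2, f3


def multisoliton_f(
    lambdas: Sequence[sp.Expr],
    sigmas: Sequence[sp.Expr] | None = None,
    x: sp.Symbol = _x,
    t: sp.Symbol = _t,
) -> sp.Expr:
    """The τ-function f = 1 + Σfᵢ for N ≤ 3 KdV solitons."""
    lambdas = tuple(sp.sympify(l) for l in lambdas)
    sigmas = tuple(sp.sympify(s) for s in (sigmas or [0] * len(lambdas)))
    ss = SolitonSet(lambdas, sigmas)
    f1, f2, f3 = ss.f_components(x, t)
    return 1 + f1 + f2 + f3


def f_to_u(f: sp.Expr, x: sp.Symbol = _x) -> sp.Expr:
    """u = 2 ∂²(ln f)/∂x², the bilinearizing substitution inverted.

    Returned unexpanded: the compact quotient form keeps downstream
    differentiation and high-precision evaluation tractable for N = 3.
    """
    return 2 * sp.diff(sp.log(f), x, 2)


def kdv_residual(u: sp.Expr, x: sp.Symbol = _x, t: sp.Symbol = _t) -> sp.Expr:
    """Left-hand side of u_t + 6uu_x + u_xxx evaluated at u."""
    return sp.diff(u, t) + 6 * u * sp.diff(u, x) + sp.diff(u, x, 3)


def verify_bilinear_chain(
    f1: sp.Expr,
    f2: sp.Expr,
    f3: sp.Expr,
    x: sp.Symbol = _x,
    t: sp.Symbol = _t,
) -> dict:
    """Check the order-by-order chain of the bilinear expansion.

    Order ε:  2(∂ₓ∂ₜ + ∂ₓ³∂ₓ... ) f₁ := 2∂ₓ(∂ₜ + ∂ₓ³) f₁ = 0
    Order ε²: same operator on f₂ equals −D_x(D_t + D_x³)(f₁·f₁)
    Order ε³: same operator on f₃ equals −D_x(D_t + D_x³)(f₁·f₂ + f₂·f₁)

    Returns the simplified residual of each order; all must be zero for a
    valid truncation (f₂ = 0 or f₃ = 0 certify the lower-N cases).
    """
    lin = lambda g: 2 * sp.diff(g, x, t) + 2 * sp.diff(g, x, 4)

    def dxdt_plus_dx4(a, b):
        return d_operator(1, 1, a, b, x, t) + d_operator(4, 0, a, b, x, t)

    r1 = sp.simplify(lin(f1))
    r2 = sp.simplify(lin(f2) + dxdt_plus_dx4(f1, f1))
    r3 = sp.simplify(lin(f3) + dxdt_plus_dx4(f1, f2) + dxdt_plus_dx4(f2, f1))
    return {
        "order1": r1,
        "order2": r2,
        "order3": r3,
        "passed": all(r == 0 for r in (r1, r2, r3)),
    }
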