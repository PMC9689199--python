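"""Composite-function derivative machinery.

Derivatives of h = f(g(ξ)) appear throughout the solver pipeline whenever the
ansatz is a polynomial of the solution of an auxiliary ODE.  Three routes are
provided:

* the single-variable Faà di Bruno formula, as an explicit sum over integer
  partitions;
* the K/Z polynomial recurrence for the squared-derivative family
  (V′)² = Σ aⱼVʲ, for which every derivative splits as
  h⁽ⁿ⁾ = Kₙ(g) + g′·Zₙ(g) with Kₙ vanishing for odd n and Zₙ for even n;
* the L polynomial recurrence for first-order polynomial auxiliary equations
  V′ = Σ cⱼVʲ, for which h⁽ⁿ⁾ = Lₙ(g).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import sympy as sp

__all__ = [
    "partition_multiplicities",
    "PartitionSpec",
    "faa_di_bruno_1d",
    "DerivativePolynomials",
    "kz_polynomials",
    "l_polynomials",
]


@lru_cache(maxsize=None)
def partition_multiplicities(n: int, k: int) -> tuple[tuple[int, ...], ...]:
    """Multiplicity vectors (λ₁,…,λₙ) with Σλᵢ = k and Σ i·λᵢ = n.

    Each vector encodes a partition of n into exactly k parts by part
    multiplicities.  Enumeration order is reverse-lexicographic for
    reproducible expression layout.
    """
    if n < 1 or k < 1 or k > n:
        return ()
    out: list[tuple[int, ...]] = []

    def rec(remaining_n: int, remaining_k: int, max_part: int, acc: dict[int, int]):
        if remaining_n == 0 and remaining_k == 0:
            lam = tuple(acc.get(i, 0) for i in range(1, n + 1))
            out.append(lam)
            return
        if remaining_n <= 0 or remaining_k <= 0:
            return
        for part in range(min(max_part, remaining_n), 0, -1):
            if part * remaining_k < remaining_n:
                break
            acc[part] = acc.get(part, 0) + 1
            rec(remaining_n - part, remaining_k - 1, part, acc)
            acc[part] -= 1

    rec(n, k, n, {})
    return tuple(out)


@dataclass(frozen=True)
class PartitionSpec:
    """The partition index set p(n, k) of the Faà di Bruno formula."""

    n: int
    k: int

    @property
    def multiplicities(self) -> tuple[tuple[int, ...], ...]:
        return partition_multiplicities(self.n, self.k)

    def __len__(self) -> int:
        return len(self.multiplicities)


def faa_di_bruno_1d(
    n: int,
    f_derivs: Sequence[sp.Expr] | Mapping[int, sp.Expr],
    g_derivs: Sequence[sp.Expr] | Mapping[int, sp.Expr],
) -> sp.Expr:
    """n-th derivative of h = f(g(x)) from the derivatives of f and g.

    ``f_derivs[k]`` is dᵏf/dgᵏ and ``g_derivs[i]`` is dⁱg/dxⁱ (index 0 unused;
    both must cover orders 1..n).  The result equals repeated direct
    differentiation.
    """
    if n < 1:
        raise ValueError("derivative order must be >= 1")

    def get(tab, i):
        return tab[i]

    total = sp.Integer(0)
    for k in range(1, n + 1):
        inner = sp.Integer(0)
        for lam in partition_multiplicities(n, k):
            term = sp.Integer(sp.factorial(n))
            for i, li in enumerate(lam, start=1):
                if li:
                    term *= get(g_derivs, i) ** li / (
                        sp.factorial(li) * sp.factorial(i) ** li
                    )
            inner += term
        total += get(f_derivs, k) * inner
    return sp.expand(total)


@dataclass(frozen=True)
class DerivativePolynomials:
    """The polynomials building h⁽ⁿ⁾ for a composite h = f(g).

    For the squared-derivative family, ``K`` and ``Z`` satisfy
    h⁽ⁿ⁾ = Kₙ(g) + g′·Zₙ(g); for first-order families ``L`` satisfies
    h⁽ⁿ⁾ = Lₙ(g).
    """

    n: int
    gen: sp.Symbol
    K: sp.Expr | None = None
    Z: sp.Expr | None = None
    L: sp.Expr | None = None


def _poly_from_coeffs(coeffs: Sequence[sp.Expr], g: sp.Symbol) -> sp.Expr:
    return sum(sp.sympify(c) * g**j for j, c in enumerate(coeffs))


def kz_polynomials(
    q: int,
    m: int,
    a_coeffs: Sequence[sp.Expr],
    b_coeffs: Sequence[sp.Expr],
    n: int,
    gen: sp.Symbol | None = None,
) -> DerivativePolynomials:
    """Kₙ, Zₙ for h = f(g), f = Σ₀^q bᵣgʳ, (g′)² = Σ₀^m aⱼgʲ.

    Recurrence: K₀ = Σ bᵣgʳ, Z₀ = 0, and
    Kₙ₊₁ = (Zₙ/2)·Σ j aⱼ g^{j−1} + Zₙ′·Σ aⱼ gʲ,  Zₙ₊₁ = Kₙ′.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if len(a_coeffs) != m + 1 or len(b_coeffs) != q + 1:
        raise ValueError("coefficient vectors must have lengths m+1 and q+1")
    g = gen if gen is not None else sp.Symbol("g")
    Q = _poly_from_coeffs(a_coeffs, g)
    Qh = sp.expand(sp.diff(Q, g) / 2)
    K = _poly_from_coeffs(b_coeffs, g)
    Z = sp.Integer(0)
    for _ in range(n):
        K, Z = (
            sp.expand(Z * Qh + sp.diff(Z, g) * Q),
            sp.expand(sp.diff(K, g)),
        )
    return DerivativePolynomials(n=n, gen=g, K=sp.expand(K), Z=sp.expand(Z))


def l_polynomials(
    q: int,
    m: int,
    c_coeffs: Sequence[sp.Expr],
    b_coeffs: Sequence[sp.Expr],
    n: int,
    gen: sp.Symbol | None = None,
) -> DerivativePolynomials:
    """Lₙ for h = f(g), f = Σ₀^q bᵣgʳ, g′ = Σ₀^m cⱼgʲ.

    L₀ = Σ bᵣgʳ and Lᵢ₊₁ = (dLᵢ/dg)·Σ cⱼgʲ; then h⁽ⁿ⁾ = Lₙ(g).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if len(c_coeffs) != m + 1 or len(b_coeffs) != q + 1:
        raise ValueError("coefficient vectors must have lengths m+1 and q+1")
    g = gen if gen is not None else sp.Symbol("g")
    C = _poly_from_coeffs(c_coeffs, g)
    L = _poly_from_coeffs(b_coeffs, g)
    for _ in range(n):
        L = sp.expand(sp.diff(L, g) * C)
    return DerivativePolynomials(n=n, gen=g, L=sp.expand(L))
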