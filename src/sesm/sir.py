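"""Exact epidemic waves for the constant-coefficient SIR model.

The Kermack–McKendrick SIR system

    dS/dt = −(τ/N)·S·I,   dI/dt = (τ/N)·S·I − ρ·I,   dR/dt = ρ·I,

with transmission rate τ (day⁻¹), recovery rate ρ (day⁻¹) and constant
population N = S + I + R, collapses to a single ODE for the recovered count:
I = (1/ρ)·dR/dt and S = S(0)·exp(−τ(R − R(0))/(ρN)) give

    dR/dt = ρ·[N − R − S(0)·exp(−τR/(ρN))]        (taking R(0) = 0).

When τ ≪ ρ the exponential may be truncated at order M; M = 2 yields a
Riccati equation dR/dt = αR² + βR + γ with an exact kink solution for R and
the classic bell-shaped (sech²) epidemic wave for I.  The general Riccati
solution adds a two-parameter correction to the bell curve.

Two Taylor conventions are supported for the truncation: ``"standard"``
keeps the 1/j! factorials of the exponential series (the default), while
``"as_printed"`` drops them, which changes α by a factor ½.  All closed
forms downstream are convention-agnostic — they consume (α, β, γ) as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "SIRParams",
    "RiccatiCoeffs",
    "EpidemicTrajectory",
    "FitReport",
    "reduce_to_R_ode",
    "particular_wave",
    "general_wave",
    "infected_from_R",
    "peak_infected",
    "full_trajectory",
    "integrate_sir",
    "synth_wave_data",
    "fit_wave",
]

_t = sp.Symbol("t")

#: ratio τ/ρ below which the truncated reduction is considered reliable
SMALL_RATIO_THRESHOLD = 0.1


@dataclass(frozen=True)
class SIRParams:
    """Epidemic parameters: rates per day, population sizes in persons.

    R(0) = 0 is assumed (no recovered individuals at the start of the wave);
    I(0) = N − S0.
    """

    tau: float
    rho: float
    N: float
    S0: float

    def __post_init__(self) -> None:
        if not (0 < self.S0 <= self.N):
            raise ValueError("require 0 < S0 <= N")
        if self.tau <= 0 or self.rho <= 0:
            raise ValueError("rates must be positive")

    @property
    def I0(self) -> float:
        return self.N - self.S0

    @property
    def small_ratio(self) -> bool:
        return self.tau / self.rho <= SMALL_RATIO_THRESHOLD


@dataclass(frozen=True)
class RiccatiCoeffs:
    """Coefficients of the truncated recovered-count ODE dR/dt = αR² + βR + γ
    (per day, persons scaled), with θ² = β² − 4αγ."""

    alpha: sp.Expr
    beta: sp.Expr
    gamma: sp.Expr
    order: int = 2
    convention: str = "standard"

    @property
    def theta2(self) -> sp.Expr:
        return sp.simplify(self.beta**2 - 4 * self.alpha * self.gamma)

    @property
    def theta(self) -> sp.Expr:
        return sp.sqrt(self.theta2)


@dataclass
class EpidemicTrajectory:
    """Time series (days) of the three compartments, plus the truncation
    defect |S_exp − (N − I − R)|/N of the exponential-form susceptible count
    against the conserving one."""

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    provenance: str
    conservation_defect: np.ndarray | None = None


def reduce_to_R_ode(
    p: SIRParams,
    M: int = 2,
    convention: Literal["standard", "as_printed"] = "standard",
) -> RiccatiCoeffs | list[sp.Expr]:
    """Truncate the recovered-count ODE at order M.

    For M = 2 returns :class:`RiccatiCoeffs`; for M > 2 returns the
    polynomial coefficient list [c₀, …, c_M] of dR/dt = Σ cⱼRʲ.  With
    ``convention="standard"`` the exponential is expanded with its 1/j!
    factors; ``"as_printed"`` drops them (so the quadratic coefficient is
    twice as large in magnitude).
    """
    if M < 2:
        raise ValueError("truncation order M must be >= 2")
    tau, rho, N, S0 = (sp.nsimplify(v, rational=True) for v in (p.tau, p.rho, p.N, p.S0))
    R = sp.Symbol("R")
    x = tau * R / (rho * N)
    if convention == "standard":
        series = sum((-x) ** j / sp.factorial(j) for j in range(M + 1))
    elif convention == "as_printed":
        series = sum((-x) ** j for j in range(M + 1))
    else:
        raise ValueError("convention must be 'standard' or 'as_printed'")
    rhs = sp.expand(rho * (N - R - S0 * series))
    poly = sp.Poly(rhs, R)
    coeffs = [poly.coeff_monomial(R**j) for j in range(M + 1)]
    if M == 2:
        return RiccatiCoeffs(coeffs[2], coeffs[1], coeffs[0], 2, convention)
    return coeffs


def particular_wave(c: RiccatiCoeffs, C: sp.Expr = sp.Symbol("C")):
    """Kink/bell pair (R(t), I(t)) from the particular Riccati solution.

    R(t) = −β/(2α) − (θ/(2α))·tanh(θ(t+C)/2) and I = (1/ρ)·dR/dt, which
    simplifies to the sech²-shaped epidemic wave.  Requires θ² > 0.  ρ is
    taken from the symbol ``rho`` unless the coefficients are numeric and a
    ρ value is attached by the caller via ``I_of``.
    """
    th2 = c.theta2
    if th2.is_number and th2 <= 0:
        raise ValueError("particular wave requires theta^2 > 0")
    th = c.theta
    R = -c.beta / (2 * c.alpha) - th / (2 * c.alpha) * sp.tanh(th * (_t + C) / 2)
    return R


def peak_infected(c: RiccatiCoeffs, rho: sp.Expr) -> sp.Expr:
    """Height of the bell curve, I at the peak time t = −C.

    Derived symbolically from I = (1/ρ)dR/dt: the peak equals −θ²/(4αρ)
    (positive, since α < 0 whenever S(0) > 0).
    """
    return sp.simplify(-c.theta2 / (4 * c.alpha * rho))


def general_wave(
    c: RiccatiCoeffs,
    C: sp.Expr = sp.Symbol("C"),
    D: sp.Expr = sp.Symbol("D"),
    E: sp.Expr = sp.Symbol("E"),
) -> sp.Expr:
    """General Riccati solution R(t) = particular + D/v(t) with

        v(t) = cosh²(θ(t+C)/2)·[E − (2αD/θ)·tanh(θ(t+C)/2)],

    which solves v′ − θ·tanh(θ(t+C)/2)·v = −αD.  D = 0 recovers the
    particular wave exactly; the denominator must not vanish on the domain
    of interest.
    """
    th = c.theta
    arg = th * (_t + C) / 2
    v = sp.cosh(arg) ** 2 * (E - 2 * c.alpha * D / th * sp.tanh(arg))
    return particular_wave(c, C) + D / v


def infected_from_R(R_form: sp.Expr, rho: sp.Expr) -> sp.Expr:
    """I(t) = (1/ρ)·dR/dt, always by symbolic differentiation."""
    return sp.diff(R_form, _t) / rho


def integrate_sir(p: SIRParams, t_grid: Sequence[float], rtol=1e-10, atol=1e-12):
    """High-accuracy numeric integration of the full (untruncated) SIR
    system, the independent oracle for the closed forms."""
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(_, y):
        S, I, R = y
        inf = p.tau / p.N * S * I
        return [-inf, inf - p.rho * I, p.rho * I]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [p.S0, p.I0, 0.0],
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        method="DOP853",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return EpidemicTrajectory(t_grid, sol.y[0], sol.y[1], sol.y[2], "numeric-ODE")


def _phase_constant(p: SIRParams, c: RiccatiCoeffs) -> float:
    """C such that R(0) = 0 for the particular wave."""
    a, b, th = float(c.alpha), float(c.beta), float(sp.sqrt(c.theta2))
    # −β/2α − (θ/2α)·tanh(θC/2) = 0  ⇒  tanh(θC/2) = −β/θ
    x = -b / th
    if not -1 < x < 1:
        raise ValueError("no phase constant yields R(0)=0 for these coefficients")
    return float(2 / th * np.arctanh(x))


def full_trajectory(
    p: SIRParams,
    t_grid: Sequence[float],
    R_form: sp.Expr | None = None,
    C: float | None = None,
) -> EpidemicTrajectory:
    """Evaluate a closed-form epidemic wave on a time grid.

    ``R_form`` defaults to the particular wave of the M = 2 reduction with
    the phase constant chosen so R(0) = 0.  I is obtained by symbolic
    differentiation, S by conservation S = N − I − R (exact by
    construction); the truncation defect against the exponential form
    S(0)·exp(−τR/(ρN)) is reported per point, not hidden.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if R_form is None:
        c = reduce_to_R_ode(p)
        Cval = C if C is not None else _phase_constant(p, c)
        R_form = particular_wave(c, sp.nsimplify(Cval, rational=True))
    I_form = infected_from_R(R_form, sp.nsimplify(p.rho, rational=True))
    Rf = sp.lambdify(_t, R_form, "numpy")
    If = sp.lambdify(_t, I_form, "numpy")
    R = np.asarray(Rf(t_grid), dtype=float)
    I = np.asarray(If(t_grid), dtype=float)
    S = p.N - I - R
    S_exp = p.S0 * np.exp(-p.tau / (p.rho * p.N) * R)
    defect = np.abs(S_exp - S) / p.N
    return EpidemicTrajectory(t_grid, S, I, R, "closed-form", defect)


def synth_wave_data(
    p: SIRParams,
    t_grid: Sequence[float],
    noise: Literal["none", "poisson", "gaussian"] = "none",
    sigma: float = 0.0,
    seed: int | None = None,
    C: float | None = None,
) -> np.ndarray:
    """Synthetic single-wave incidence series I(t) on the grid.

    Emulates surveillance counts of currently infected individuals during
    one outbreak wave: the deterministic closed-form bell curve, optionally
    with Poisson count noise or additive Gaussian noise (σ in persons).
    ``C`` shifts the wave in time (default: the phase with R(0) = 0, which
    places the observation window on the declining limb); the peak sits at
    t = −C.  Counts are never negative; stochastic output is reproducible
    by seed.
    """
    traj = full_trajectory(p, t_grid, C=C)
    I = traj.I
    if noise == "none":
        return I
    rng = np.random.default_rng(seed)
    if noise == "poisson":
        return rng.poisson(np.clip(I, 0, None)).astype(float)
    if noise == "gaussian":
        return np.clip(I + rng.normal(0.0, sigma, size=I.shape), 0.0, None)
    raise ValueError("noise must be 'none', 'poisson' or 'gaussian'")


@dataclass(frozen=True)
class FitReport:
    """Least-squares fit of the bell-curve model to an incidence series."""

    alpha: float
    beta: float
    gamma: float
    C: float
    D: float
    E: float
    residual_norm: float
    n_points: int
    success: bool
    message: str


def _sech2(arg):
    a = np.clip(np.abs(arg), 0.0, 350.0)
    return (2.0 * np.exp(-a) / (1.0 + np.exp(-2.0 * a))) ** 2


def _model_I(v, t, rho, model, alpha_of):
    """Bell-curve model in the well-conditioned parameters (A, θ, C) with
    A = peak height and θ = inverse width; α is recovered via ``alpha_of``."""
    A, th, C = v[:3]
    if A <= 0 or th <= 0:
        return np.full_like(t, 1e12)
    arg = th * (t + C) / 2
    I = A * _sech2(arg)
    if model == "general":
        alpha = alpha_of(A, th)
        D, E = v[3], v[4]
        tanh = np.tanh(arg)
        cosh2 = 1.0 / np.maximum(_sech2(arg), 1e-300)
        den = cosh2 * (E - 2 * alpha * D / th * tanh)
        if np.any(np.abs(den) < 1e-12):
            return np.full_like(t, 1e12)
        dv = cosh2 * tanh * th * (E - 2 * alpha * D / th * tanh) - alpha * D
        I = I - D * dv / (rho * den**2)
    return I


def fit_wave(
    t: Sequence[float],
    series: Sequence[float],
    rho: float,
    gamma: float,
    init: Mapping[str, float],
    model: Literal["particular", "general"] = "particular",
) -> FitReport:
    """Nonlinear least squares on the closed-form epidemic wave.

    Fits (α, β, C) — plus (D, E) for the general model — with γ supplied:
    the incidence curve alone determines only the peak height, width and
    centre, i.e. (α, θ, C); γ = ρ(N − S(0)) is demographic information the
    fitter treats as known, which makes β = ±√(θ² + 4αγ) identifiable.
    Raises on degenerate input; reports convergence honestly.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(series, dtype=float)
    n_par = 3 if model == "particular" else 5
    if len(y) < n_par:
        raise ValueError("series shorter than the number of fit parameters")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate (constant) incidence series")

    # internal parametrization: A = −θ²/(4αρ) (peak height), θ, C
    a0, b0, C0 = init["alpha"], init["beta"], init["C"]
    th0 = float(np.sqrt(b0**2 - 4 * a0 * gamma))
    A0 = float(-(th0**2) / (4 * a0 * rho))
    beta_sign = -1.0 if b0 < 0 else 1.0

    def alpha_of(A, th):
        return -(th**2) / (4 * A * rho)

    x0 = [A0, th0, C0] + ([init["D"], init["E"]] if model == "general" else [])
    x0 = np.array(x0, dtype=float)

    def resid(v):
        return _model_I(v, t, rho, model, alpha_of) - y

    res = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    A, th, C = res.x[:3]
    alpha = alpha_of(A, th)
    disc = th**2 + 4 * alpha * gamma
    beta = beta_sign * float(np.sqrt(disc)) if disc >= 0 else float("nan")
    return FitReport(
        alpha=float(alpha),
        beta=beta,
        gamma=gamma,
        C=float(C),
        D=float(res.x[3]) if model == "general" else 0.0,
        E=float(res.x[4]) if model == "general" else 1.0,
        residual_norm=float(np.linalg.norm(res.fun)),
        n_points=len(y),
        success=bool(res.success) and np.isfinite(beta),
        message=str(res.message),
    )
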