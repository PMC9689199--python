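# Methods

This note documents the models and numerical conventions behind `sesm`: what
each subsystem computes, the assumptions it makes, the tunable parameters and
their defaults, and what the shipped tests do and do not establish.

## The solution pipeline

`sesm` constructs exact traveling-wave solutions of nonlinear ODEs/PDEs by a
four-stage procedure:

1. **Transformation.** If the equation carries a non-polynomial nonlinearity
   N(u) (exponential, trigonometric, hyperbolic, or an integer power of one),
   a substitution u = T(F) from the shipped catalog
   (`data/transform_catalog.json`) rewrites it so that N and all derivatives
   of u become rational in F. Multiplying by a minimal clearing factor — a
   power of F, 1+F², or 1−F² — leaves a polynomial equation; the factor is
   returned so the zero set can be excluded from solution domains. Inverse
   maps use principal branches of arctan/artanh.
2. **Ansatz.** The solution is posed as a polynomial
   u(ξ) = Σ θ_μ V(ξ)^μ in the solution V of an *auxiliary (simple) equation*
   — a first-order ODE with known closed forms (Bernoulli, Riccati, extended
   tanh, a generic polynomial right-hand side) or a squared-derivative
   polynomial family (V′)² = Σ aⱼVʲ whose solutions include hyperbolic,
   trigonometric and elliptic profiles. Separable product ansätze
   F = A·T₁(αx)·T₂(γt) over two squared-derivative equations are supported
   for standing waves. Laurent ansätze (negative powers) are an opt-in mode;
   the default non-negative range covers every shipped example.
3. **Balance.** Writing each term's top V-degree as an affine function of the
   ansatz degree L and the auxiliary-equation degree β (an n-th ξ-derivative
   adds n(β−1)), a candidate (L, β) is *admissible* when the maximal degree is
   attained by at least two terms, so the leading coefficient relation can
   vanish nontrivially. `compute_balance` returns **all** admissible
   candidates within the integer bounds, not only the minimal one: a
   non-minimal admissible degree can carry solutions whose surplus
   coefficients are zeroed by the algebraic system (the separable
   standing-wave example selects degree 4 this way).
4. **Algebraic system and assembly.** Substituting the ansatz, eliminating
   every derivative of V through the auxiliary equation, and collecting
   powers of V yields a nonlinear algebraic system in the ansatz coefficients
   and equation parameters; each nontrivial solution of the system, combined
   with a closed-form branch of the auxiliary equation, assembles into an
   exact solution. For squared-derivative families (V′)² is rewritten through
   the defining polynomial immediately, so V′ never appears above the first
   power and the reduced equation splits as W₀(V) + V′·W₁(V) = 0.

The same machinery runs in the inverse direction
(`derive_equation_constraints`): given a prescribed composite form, it
constrains a template equation's symbolic coefficients so the form is an
exact solution.

### Derivative bookkeeping

Derivatives of composite functions h = f(g(ξ)) are handled three ways, which
are tested against each other and against explicit solutions:

* the single-variable Faà di Bruno formula as a sum over integer partitions
  (partition enumeration is memoized; term order is reverse-lexicographic for
  reproducible layout);
* the K/Z recurrence for (g′)² = Σ aⱼgʲ: every derivative splits as
  h⁽ⁿ⁾ = Kₙ(g) + g′·Zₙ(g), with Kₙ ≡ 0 for odd n and Zₙ ≡ 0 for even n
  (checked computationally through order 6);
* the L recurrence for g′ = Σ cⱼgʲ: h⁽ⁿ⁾ = Lₙ(g).

The closed forms of K₄ (triple sum with coefficient
(jr/2 + r(r−1))(j+r−2)(u/2 + j+r−3)) and L₃ (quadruple sum with coefficient
r(r+j−1)(r+j+k−2)) were re-derived from the recurrences and are frozen in the
test suite. The multivariate version of the formula is not implemented: the
two-variable product ansatz needs only ordinary chain rules.

### Solving and verification

Systems are solved symbolically with staged strategies: imposed structural
hints (e.g. zeroing a surplus coefficient) first, then `sympy.solve`; every
returned assignment is verified by back-substitution before being reported
(this caught a spurious root in the quartic-nonlinearity family). All
solutions are returned in a canonical order; all-zero-ansatz assignments are
flagged trivial, never silently dropped, and a one-term relation (an
unbalanced configuration) stays in the system as a visible constraint.

`verify_solution` certifies closed forms in two stages: symbolic residual
simplification first; if that fails, a high-precision numeric residual at 16
sampled rational points (seeded; default seed 1653) evaluated at 50
significant digits, passing when |residual| / max(1, largest term magnitude)
< 10⁻³⁰ at every point. Sampling that only hits singularities is reported as
inconclusive, not as a pass. Inequality conditions attached to branches
(sign constraints, clearing-factor zero sets) are carried along and
spot-checked at witness points; they are not used to prune symbolic solving.

### The solution registry

`sesm.catalog` ships 24 solution records as JSON data files. Each is checked
two ways at test time: the stored parameter tuple must annihilate the
algebraic system *generated from scratch* by the engine (an anti-drift check
on system generation), and the assembled closed form must pass residual
verification. Records whose provenance text was unreliable carry their
tuples as the package's own derivation (staged elimination of the generated
system), and several record structural facts the derivation exposed — e.g.
that a genuinely quadratic tanh ansatz in a cubic template forces the cubic
and convective-product coefficients to vanish, and that the quartic
reaction-diffusion family constrains the wave speed through the cubic
coefficient. Entries are data, not code; new fixtures need no source
changes.

## Hirota bridge

For the KdV equation u_t + 6uu_x + u_xxx = 0 the substitution
u = 2∂²(ln f)/∂x² produces the bilinear form (D_xD_t + D_x⁴)(f·f) = 0, with
the D-operators implemented directly from their double-sum definition. The
expansion f = 1 + εf₁ + ε²f₂ + ε³f₃ yields one linear equation per order of
ε; exponential auxiliary solutions exp(λᵢx − λᵢ³t + σᵢ) solve the chain with
interaction coefficients a_ij = (λᵢ−λⱼ)²/(λᵢ+λⱼ)² and b₁₂₃ = a₁₂a₁₃a₂₃, and
the chain truncates exactly for N ≤ 3. ε is set to 1 and absorbed into the
phases; the order-by-order equations are still verified separately.
Multisoliton profiles keep the compact log-derivative quotient form — the
expanded rational function is enormous for N = 3 — and residuals are
evaluated through compiled mpmath at 60 working digits.

## SIR epidemic waves

The constant-coefficient SIR model (transmission rate τ, recovery rate ρ,
both per day; constant population N) collapses to one ODE for the recovered
count R via I = (1/ρ)dR/dt and S = S(0)·exp(−τ(R−R(0))/(ρN)), with R(0) = 0
assumed. In the small-ratio regime τ/ρ ≪ 1 (flag threshold 0.1) the
exponential is truncated at order M; M = 2 gives the Riccati equation
dR/dt = αR² + βR + γ with

* standard convention: γ = ρ(N−S₀), β = τS₀/N − ρ, α = −τ²S₀/(2ρN²);
* an alternative "as_printed" convention without the 1/j! factors, whose α
  is twice as large. Both are provided because both appear in the applied
  literature; everything downstream consumes (α, β, γ) as given. M > 2
  returns the polynomial coefficient list for the ansatz machinery.

The particular solution R = −β/(2α) − (θ/(2α))tanh(θ(t+C)/2), θ² = β²−4αγ,
gives the bell-shaped wave I(t); I is always obtained by symbolic
differentiation of R, never transcribed, which fixes the peak value at
I(−C) = −θ²/(4αρ) (positive since α < 0). The general Riccati solution adds
D/v(t) with v solving a first-order linear ODE; it reduces exactly to the
particular wave at D = 0 and shifts the peak by αD²/(ρE²).

Evaluated trajectories take S from conservation (S = N − I − R, exact by
construction) and report the truncation defect |S₀e^{−τR/(ρN)} − S|/N per
point rather than hiding it. The independent oracle is DOP853 integration of
the untruncated system at rtol 10⁻¹⁰, atol 10⁻¹²; for the reference regime
τ/ρ = 0.05, N = 10⁴, S₀ = 9·10³ the closed form agrees with it to a
calibrated relative L∞ bound of 10⁻⁶ over 25 days.

### Synthetic incidence data and fitting

`synth_wave_data` emulates surveillance counts of a single outbreak wave:
the deterministic closed-form I(t) on a day grid, optionally with Poisson
count noise or additive Gaussian noise (clipped at zero), reproducible by
seed. The defaults are the reference regime above with the phase fixed by
R(0) = 0; the phase constant C may be overridden to place the peak inside
the observation window. The generator emulates a noisy deterministic bell
curve only — no reporting delays, day-of-week effects, multi-wave mixtures
or parameter drift — so passing tests demonstrate estimator correctness on
the model class, not robustness on real surveillance data.

`fit_wave` is nonlinear least squares (Levenberg–Marquardt) on the
closed-form curve. The incidence series alone identifies only the peak
height, width and centre, i.e. (α, θ, C); the fitter therefore works
internally in those well-conditioned coordinates and treats γ = ρ(N−S₀) as
known demographic information, which makes β = ±√(θ²+4αγ) identifiable (the
sign is taken from the initial guess). Degenerate input (constant series,
fewer points than parameters) raises; convergence is reported honestly.

## Expression grammar

Stored expressions are exact: rational constants only (decimal literals are
converted on parse), a whitelist of function names, no floats. ASCII infix
syntax with `^` for powers, function-call syntax, `;` comments. EBNF:

```
expr     = term , { ("+" | "-") , term } ;
term     = factor , { ("*" | "/") , factor } ;
factor   = base , [ "^" , factor ] | ("+" | "-") , factor ;
base     = number | symbol | call | "(" , expr , ")" ;
call     = name , "(" , expr , { "," , expr } , ")" ;
number   = integer | integer , "/" , integer | decimal ;   (* decimal → exact rational *)
symbol   = letter , { letter | digit | "_" } ;
name     = "exp" | "log" | "ln" | "sqrt" | "sin" | "cos" | "tan" | "cot"
         | "sinh" | "cosh" | "tanh" | "coth" | "sech" | "csch"
         | "arctan" | "atan" | "arccot" | "acot" | "artanh" | "atanh"
         | "arcoth" | "acoth" | "sn" | "cn" | "dn" | "wp" | "Abs"
         | "conjugate" | "Derivative" | "diff" ;
```

Names such as `gamma` or `beta` parse as plain symbols, never as special
functions. Jacobi sn/cn/dn evaluate numerically through mpmath; the
Weierstrass symbol `wp` is symbolic only (general evaluation of the implicit
squared-derivative special function would be its own project — numeric
evaluation is provided exactly for the named degenerations: exponential,
hyperbolic, trigonometric, Jacobi).

## Design choices and limitations

* Canonical form everywhere: fully expanded polynomials, monomials ordered
  by descending degree, deterministic relation order — systems are
  reproducible across runs.
* Branch signs (±) are enumerated into distinct solution branches rather
  than carried symbolically; integration constants ξ₀ stay symbolic by
  default.
* The balance search, system generation and solving are exercised on
  second- to fifth-degree nonlinearities and up to fourth-order derivatives;
  nothing prevents larger inputs, but solver time grows quickly and the
  per-call `sympy.solve` has no internal timeout — heavy systems are solved
  by staged elimination instead (the registry stores those tuples frozen).
* PDEs in more than two independent variables, proofs of completeness of a
  solution set, and N > 3 solitons are out of scope.
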