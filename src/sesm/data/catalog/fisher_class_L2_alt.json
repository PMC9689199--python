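{
  "id": "fisher-class-L2-alt",
  "tags": [
    "bernoulli",
    "reaction-diffusion"
  ],
  "workflow": "power_series",
  "reference": "Second kink solution of the quadratic reaction-diffusion traveling-wave ODE: the wave-number and equation coefficients are constrained instead of the ansatz offset.",
  "equation": {
    "lhs": "nu1*Derivative(Q(xi),xi,xi) + nu2*Derivative(Q(xi),xi) + mu2*Q(xi)^2 + mu1*Q(xi)",
    "unknown": "Q",
    "vars": [
      "xi"
    ],
    "params": [
      "nu1",
      "nu2",
      "mu1",
      "mu2"
    ]
  },
  "ansatz": {
    "degree": 2,
    "coeff": "a"
  },
  "simple_equation": {
    "family": "bernoulli",
    "params": {
      "a": "a",
      "b": "b",
      "k": 2
    }
  },
  "parameter_solution": {
    "a0": "a1^2/(4*a2)",
    "nu2": "5*mu1/(6*a)",
    "mu2": "-4*mu1*a2/a1^2",
    "b": "2*a*a2/a1"
  },
  "remaining": {
    "nu1": "mu1/(6*a^2)"
  },
  "branch": 0,
  "witness": {
    "a": "1",
    "a1": "1",
    "a2": "-1",
    "mu1": "3",
    "xi0": "0"
  },
  "notes": "the consistency condition nu1 = mu1/(6 a^2), implied by the system, is recorded explicitly"
}
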