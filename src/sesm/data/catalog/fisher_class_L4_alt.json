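{
  "id": "fisher-class-L4-alt",
  "tags": [
    "bernoulli",
    "reaction-diffusion"
  ],
  "workflow": "power_series",
  "reference": "Second degree-4 solution of the quadratic reaction-diffusion ODE, with nonzero constant, quadratic and quartic ansatz terms.",
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
    "degree": 4,
    "coeff": "a"
  },
  "simple_equation": {
    "family": "bernoulli",
    "params": {
      "a": "a",
      "b": "b",
      "k": 3
    }
  },
  "parameter_solution": {
    "a4": "a2*b/(2*a)",
    "a3": "0",
    "a1": "0",
    "a0": "a*a2/(2*b)",
    "mu1": "12*a*nu2/5",
    "mu2": "-24*b*nu2/(5*a2)",
    "nu1": "nu2/(10*a)"
  },
  "branch": 1,
  "conditions": [
    "b > 0",
    "a < 0"
  ],
  "witness": {
    "a": "-1",
    "b": "1",
    "a2": "1",
    "nu2": "1",
    "xi0": "0"
  }
}
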