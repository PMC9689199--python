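{
  "id": "huxley-class-L2",
  "tags": [
    "bernoulli",
    "huxley"
  ],
  "workflow": "power_series",
  "reference": "Degree-2 ansatz over the Bernoulli equation with k=3 for the cubic-nonlinearity ODE; the linear and quadratic equation coefficients are constrained, the wave-number stays free.",
  "equation": {
    "lhs": "nu1*Derivative(Q(xi),xi,xi) + nu2*Derivative(Q(xi),xi) + mu3*Q(xi)^3 + mu2*Q(xi)^2 + mu1*Q(xi)",
    "unknown": "Q",
    "vars": [
      "xi"
    ],
    "params": [
      "nu1",
      "nu2",
      "mu1",
      "mu2",
      "mu3"
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
      "k": 3
    }
  },
  "derive_first": true,
  "hints": {
    "a1": "0"
  },
  "solve_for": [
    "a0",
    "a2",
    "mu1",
    "mu2"
  ],
  "select_nonzero": [
    "a0",
    "a2"
  ],
  "solution_index": 0,
  "branch": 0,
  "conditions": [
    "a > 0",
    "b < 0"
  ],
  "witness": {
    "a": "1",
    "b": "-1",
    "nu1": "1",
    "mu3": "-1",
    "nu2": "1",
    "xi0": "0"
  },
  "reproduce": true
}
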