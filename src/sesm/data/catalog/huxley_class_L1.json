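{
  "id": "huxley-class-L1",
  "tags": [
    "bernoulli",
    "huxley"
  ],
  "workflow": "power_series",
  "reference": "Linear ansatz over the Bernoulli equation with k=2 for the cubic-nonlinearity (Huxley class) traveling-wave ODE; tuple re-derived by solving the generated system.",
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
    "degree": 1,
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
  "derive_first": true,
  "hints": {
    "a0": "0"
  },
  "solve_for": [
    "a1",
    "a",
    "mu1"
  ],
  "select_nonzero": [
    "a1"
  ],
  "solution_index": 0,
  "branch": 1,
  "conditions": [
    "b > 0",
    "a < 0"
  ],
  "witness": {
    "b": "1",
    "nu1": "1",
    "mu3": "-2",
    "mu2": "1",
    "nu2": "3",
    "xi0": "0"
  },
  "reproduce": true
}
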