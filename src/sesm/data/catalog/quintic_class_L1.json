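{
  "id": "quintic-class-L1",
  "tags": [
    "bernoulli",
    "population-migration"
  ],
  "workflow": "power_series",
  "reference": "Linear ansatz over the Bernoulli equation with k=3 for the quintic-nonlinearity ODE; all five nonlinearity coefficients are expressed through the free ansatz coefficients.",
  "equation": {
    "lhs": "nu1*Derivative(Q(xi),xi,xi) + nu2*Derivative(Q(xi),xi) + mu5*Q(xi)^5 + mu4*Q(xi)^4 + mu3*Q(xi)^3 + mu2*Q(xi)^2 + mu1*Q(xi)",
    "unknown": "Q",
    "vars": [
      "xi"
    ],
    "params": [
      "nu1",
      "nu2",
      "mu1",
      "mu2",
      "mu3",
      "mu4",
      "mu5"
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
      "k": 3
    }
  },
  "derive_first": true,
  "solve_for": [
    "mu1",
    "mu2",
    "mu3",
    "mu4",
    "mu5",
    "a"
  ],
  "select_nonzero": [
    "mu5"
  ],
  "solution_index": 0,
  "branch": 0,
  "conditions": [
    "b < 0",
    "a > 0"
  ],
  "witness": {
    "a0": "1",
    "a1": "1",
    "b": "-1",
    "nu1": "1",
    "nu2": "1",
    "xi0": "0"
  },
  "reproduce": true
}
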