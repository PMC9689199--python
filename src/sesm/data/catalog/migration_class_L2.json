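{
  "id": "migration-class-L2",
  "tags": [
    "bernoulli",
    "population-migration"
  ],
  "workflow": "power_series",
  "reference": "Degree-2 ansatz over the Bernoulli equation with k=4 for the quartic-nonlinearity ODE from population-migration models; the solution carries a 2/3 fractional power of the kink profile.",
  "equation": {
    "lhs": "nu1*Derivative(Q(xi),xi,xi) + nu2*Derivative(Q(xi),xi) + mu4*Q(xi)^4 + mu3*Q(xi)^3 + mu2*Q(xi)^2 + mu1*Q(xi)",
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
      "mu4"
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
      "k": 4
    }
  },
  "derive_first": true,
  "hints": {
    "a1": "0"
  },
  "solve_for": [
    "a0",
    "a2",
    "a",
    "nu2",
    "mu1",
    "mu2"
  ],
  "select_nonzero": [
    "a2"
  ],
  "select_real": true,
  "solution_index": 1,
  "branch": 1,
  "conditions": [
    "b > 0",
    "a < 0"
  ],
  "witness": {
    "nu1": "1",
    "b": "1",
    "mu4": "-1",
    "mu3": "-1",
    "xi0": "0"
  },
  "reproduce": true,
  "notes": "the wave speed combination nu2 is constrained together with the coefficients: top-degree consistency links it to mu3"
}
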