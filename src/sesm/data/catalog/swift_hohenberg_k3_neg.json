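{
  "id": "swift-hohenberg-bernoulli-k3-neg",
  "tags": [
    "swift-hohenberg",
    "bernoulli"
  ],
  "workflow": "power_series",
  "reference": "Quintic generalized Swift-Hohenberg traveling wave, degree-2 ansatz over the Bernoulli equation with k=3 (decaying-exponential branch).",
  "equation": {
    "lhs": "-v*Derivative(u(xi),xi) + 2*Derivative(u(xi),xi,xi) + Derivative(u(xi),xi,xi,xi,xi) - c0 - c1*u(xi) - c2*u(xi)^2 - c3*u(xi)^3 - c4*u(xi)^4 - c5*u(xi)^5",
    "unknown": "u",
    "vars": [
      "xi"
    ],
    "params": [
      "v",
      "c0",
      "c1",
      "c2",
      "c3",
      "c4",
      "c5"
    ]
  },
  "ansatz": {
    "degree": 2,
    "coeff": "theta"
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
    "theta1": "0"
  },
  "solve_for": [
    "c0",
    "c1",
    "c2",
    "c3",
    "c4",
    "c5"
  ],
  "solution_index": 0,
  "branch": 1,
  "conditions": [
    "b > 0",
    "a < 0"
  ],
  "witness": {
    "a": "-1",
    "b": "1",
    "v": "1",
    "theta0": "1/2",
    "theta2": "1",
    "xi0": "0"
  },
  "reproduce": true
}
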