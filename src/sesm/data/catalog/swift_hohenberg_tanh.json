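{
  "id": "swift-hohenberg-tanh",
  "tags": [
    "swift-hohenberg",
    "tanh"
  ],
  "workflow": "power_series",
  "reference": "Quintic generalized Swift-Hohenberg traveling wave, linear ansatz over the b=0 Riccati (extended tanh) equation; the quintic coefficients are fixed by the ansatz (inverse direction), theta0/theta1 and the wave speed stay free.",
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
    "degree": 1,
    "coeff": "theta"
  },
  "simple_equation": {
    "family": "riccati",
    "params": {
      "a": "a",
      "b": 0,
      "c": "c"
    }
  },
  "derive_first": true,
  "solve_for": [
    "c0",
    "c1",
    "c2",
    "c3",
    "c4",
    "c5"
  ],
  "solution_index": 0,
  "branch": 0,
  "conditions": [
    "a*c < 0"
  ],
  "witness": {
    "a": "-1",
    "c": "1",
    "v": "1",
    "theta0": "1/2",
    "theta1": "1",
    "xi0": "0"
  },
  "reproduce": true
}
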