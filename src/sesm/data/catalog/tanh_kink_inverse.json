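{
  "id": "tanh-kink-inverse",
  "tags": [
    "inverse",
    "tanh"
  ],
  "workflow": "power_series",
  "reference": "Inverse construction: coefficients of a second-order ODE with cubic nonlinearity and convective term constrained so that a linear function of the tanh kink solves it.",
  "equation": {
    "lhs": "q1*Derivative(F(xi),xi,xi) + q2*F(xi)*Derivative(F(xi),xi) + q3*F(xi)^3 + q4*F(xi)^2 + q5*F(xi)",
    "unknown": "F",
    "vars": [
      "xi"
    ],
    "params": [
      "q1",
      "q2",
      "q3",
      "q4",
      "q5"
    ]
  },
  "ansatz": {
    "degree": 1,
    "coeff": "p"
  },
  "simple_equation": {
    "family": "extended_tanh",
    "params": {
      "abar": "a",
      "cbar": "b"
    }
  },
  "parameter_solution": {
    "q3": "a^2*(p1*q2 - 2*a^2*q1)/p1^2",
    "q4": "-2*a^2*p0*(p1*q2 - 3*a^2*q1)/p1^2",
    "q5": "-4*a^4*p0^2*q1/p1^2",
    "b": "a*p0/p1"
  },
  "branch": 0,
  "witness": {
    "a": "1",
    "p0": "1",
    "p1": "2",
    "q1": "1",
    "q2": "1",
    "xi0": "0"
  },
  "reproduce": false
}
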