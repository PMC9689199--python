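{
  "id": "tanh-quadratic-inverse",
  "tags": [
    "inverse",
    "tanh"
  ],
  "workflow": "power_series",
  "reference": "Inverse construction with a quadratic function of the tanh kink: top-degree matching forces the cubic and convective-product coefficients to vanish, leaving a quadratic-nonlinearity ODE solved by a kink on a pedestal.",
  "equation": {
    "lhs": "q1*Derivative(F(xi),xi,xi) + q2*F(xi)*Derivative(F(xi),xi) + q3*Derivative(F(xi),xi) + q4*F(xi)^3 + q5*F(xi)^2 + q6*F(xi) + q7",
    "unknown": "F",
    "vars": [
      "xi"
    ],
    "params": [
      "q1",
      "q2",
      "q3",
      "q4",
      "q5",
      "q6",
      "q7"
    ]
  },
  "ansatz": {
    "degree": 2,
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
    "q2": "0",
    "q4": "0",
    "b": "a*p1/(2*p2)",
    "q3": "-5*a^2*p1*q1/p2",
    "q5": "-6*a^4*q1/p2",
    "q6": "3*a^4*q1*(4*p0*p2 + p1^2)/p2^2",
    "q7": "-3*a^4*q1*(4*p0*p2 - p1^2)*(4*p0*p2 + 3*p1^2)/(8*p2^3)"
  },
  "branch": 0,
  "witness": {
    "a": "1",
    "p0": "1",
    "p1": "1",
    "p2": "1",
    "q1": "1",
    "xi0": "0"
  },
  "reproduce": false
}
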