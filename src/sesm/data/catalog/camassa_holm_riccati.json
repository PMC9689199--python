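{
  "id": "camassa-holm-riccati",
  "tags": [
    "camassa-holm",
    "riccati"
  ],
  "workflow": "power_series",
  "reference": "Generalized Camassa-Holm traveling wave with linear dispersive flux, degree-2 ansatz over the full Riccati equation; the top-degree relation forces p3 = p4 p5/5.",
  "equation": {
    "lhs": "(p1 - v)*Derivative(U(xi),xi) + p2*v*Derivative(U(xi),xi,xi,xi) - p3*Derivative(q1*U(xi) + q2*U(xi)^2, xi, xi, xi) + p4*Derivative(r1*U(xi)/2 + p5*q2*Derivative(U(xi),xi)^2, xi)",
    "unknown": "U",
    "vars": [
      "xi"
    ],
    "params": [
      "v",
      "p1",
      "p2",
      "p3",
      "p4",
      "p5",
      "q1",
      "q2",
      "r1"
    ]
  },
  "ansatz": {
    "degree": 2,
    "coeff": "theta"
  },
  "simple_equation": {
    "family": "riccati",
    "params": {
      "a": "a",
      "b": "b",
      "c": "c"
    }
  },
  "parameter_solution": {
    "p3": "p4*p5/5",
    "theta0": "(160*a^2*c^2*p2*v - 32*a^2*c^2*p4*p5*q1 - 80*a*b^2*c*p2*v + 16*a*b^2*c*p4*p5*q1 + 80*a*c*p1 + 40*a*c*p4*r1 - 80*a*c*v + 10*b^4*p2*v - 2*b^4*p4*p5*q1 + 10*b^2*p1 + 5*b^2*p4*r1 - 10*b^2*v)/(4*p4*p5*q2*(4*a*c - b^2)^2)",
    "theta1": "15*a*b*(2*p1 + p4*r1 - 2*v)/(p4*p5*q2*(4*a*c - b^2)^2)",
    "theta2": "15*a^2*(2*p1 + p4*r1 - 2*v)/(p4*p5*q2*(4*a*c - b^2)^2)"
  },
  "branch": 0,
  "conditions": [
    "b^2 - 4*a*c > 0"
  ],
  "witness": {
    "a": "1",
    "b": "1",
    "c": "-1",
    "v": "1",
    "p1": "1",
    "p2": "1",
    "p4": "1",
    "p5": "1",
    "q1": "1",
    "q2": "1",
    "r1": "1",
    "xi0": "0"
  }
}
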