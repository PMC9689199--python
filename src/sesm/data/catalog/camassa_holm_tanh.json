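{
  "id": "camassa-holm-tanh",
  "tags": [
    "camassa-holm",
    "tanh"
  ],
  "workflow": "power_series",
  "reference": "Generalized Camassa-Holm traveling wave with quadratic dispersive flux, degree-2 ansatz over the b=0 Riccati (extended tanh) equation; theta1 = 0 and p3 = p4 p5/5 are forced.",
  "equation": {
    "lhs": "(p1 - v)*Derivative(U(xi),xi) + p2*v*Derivative(U(xi),xi,xi,xi) - p3*Derivative(q1*U(xi) + q2*U(xi)^2, xi, xi, xi) + p4*Derivative(r1*U(xi)/2 + r2*U(xi)^2/2 + p5*q2*Derivative(U(xi),xi)^2, xi)",
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
      "r1",
      "r2"
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
      "b": 0,
      "c": "c"
    }
  },
  "parameter_solution": {
    "p3": "p4*p5/5",
    "theta1": "0",
    "theta0": "(320*a^2*c^2*p2*p5*q2*v - 64*a^2*c^2*p4*p5^2*q1*q2 + 160*a*c*p1*p5*q2 + 400*a*c*p2*r2*v - 80*a*c*p4*p5*q1*r2 + 80*a*c*p4*p5*q2*r1 - 160*a*c*p5*q2*v + 50*p1*r2 + 25*p4*r1*r2 - 50*r2*v)/(2*p4*(8*a*c*p5*q2 - 5*r2)*(8*a*c*p5*q2 + 5*r2))",
    "theta2": "60*a^2*(2*p1*p5*q2 + 5*p2*r2*v - p4*p5*q1*r2 + p4*p5*q2*r1 - 2*p5*q2*v)/(p4*(8*a*c*p5*q2 - 5*r2)*(8*a*c*p5*q2 + 5*r2))"
  },
  "branch": 0,
  "conditions": [
    "a*c < 0"
  ],
  "witness": {
    "a": "-1",
    "c": "1",
    "v": "1",
    "p1": "1",
    "p2": "1",
    "p4": "1",
    "p5": "1",
    "q1": "1",
    "q2": "1",
    "r1": "1",
    "r2": "1",
    "xi0": "0"
  }
}
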