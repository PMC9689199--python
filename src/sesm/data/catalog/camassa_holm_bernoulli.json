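{
  "id": "camassa-holm-bernoulli",
  "tags": [
    "camassa-holm",
    "bernoulli"
  ],
  "workflow": "power_series",
  "reference": "Generalized Camassa-Holm traveling wave (cubic flux, quadratic dispersive flux), degree-2 ansatz over the Bernoulli equation with k=2; tuple obtained by staged elimination of the 7-relation system (growing branch).",
  "equation": {
    "lhs": "(p1 - v)*Derivative(U(xi),xi) + p2*v*Derivative(U(xi),xi,xi,xi) - p3*Derivative(q1*U(xi) + q2*U(xi)^2, xi, xi, xi) + p4*Derivative((r1*U(xi) + r2*U(xi)^2 + r3*U(xi)^3)/2 + p5*q2*Derivative(U(xi),xi)^2, xi)",
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
      "r2",
      "r3"
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
      "k": 2
    }
  },
  "parameter_solution": {
    "theta2": "8*b^2*q2*(5*p3 - p4*p5)/(p4*r3)",
    "theta1": "8*a*b*q2*(5*p3 - p4*p5)/(p4*r3)",
    "theta0": "-(-80*a^2*p3^2*q2^2 + 36*a^2*p3*p4*p5*q2^2 - 4*a^2*p4^2*p5^2*q2^2 + 3*p2*p4*r3*v - 3*p3*p4*q1*r3 + 10*p3*p4*q2*r2 - 2*p4^2*p5*q2*r2)/(6*p4*q2*r3*(4*p3 - p4*p5))",
    "r1": "-(3840*a^4*p3^4*q2^4 - 3968*a^4*p3^3*p4*p5*q2^4 + 1520*a^4*p3^2*p4^2*p5^2*q2^4 - 256*a^4*p3*p4^3*p5^3*q2^4 + 16*a^4*p4^4*p5^4*q2^4 + 384*p1*p3^2*p4*q2^2*r3 - 192*p1*p3*p4^2*p5*q2^2*r3 + 24*p1*p4^3*p5^2*q2^2*r3 + 9*p2^2*p4^2*r3^2*v^2 - 18*p2*p3*p4^2*q1*r3^2*v + 12*p2*p3*p4^2*q2*r2*r3*v + 9*p3^2*p4^2*q1^2*r3^2 - 12*p3^2*p4^2*q1*q2*r2*r3 - 60*p3^2*p4^2*q2^2*r2^2 - 384*p3^2*p4*q2^2*r3*v + 32*p3*p4^3*p5*q2^2*r2^2 + 192*p3*p4^2*p5*q2^2*r3*v - 4*p4^4*p5^2*q2^2*r2^2 - 24*p4^3*p5^2*q2^2*r3*v)/(12*p4^2*q2^2*r3*(4*p3 - p4*p5)^2)"
  },
  "branch": 0,
  "conditions": [
    "b < 0",
    "a > 0"
  ],
  "witness": {
    "a": "1",
    "b": "-1",
    "v": "1",
    "p1": "1",
    "p2": "1",
    "p3": "1",
    "p4": "1",
    "p5": "1",
    "q1": "1",
    "q2": "1",
    "r2": "1",
    "r3": "1",
    "xi0": "0"
  }
}
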