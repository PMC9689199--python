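{
  "id": "rayleigh-tanh",
  "tags": [
    "rayleigh",
    "tanh"
  ],
  "workflow": "power_series",
  "reference": "Cubic generalized Rayleigh traveling wave with quadratic velocity nonlinearity, degree-2 ansatz over the b=0 Riccati equation; tuple obtained by staged elimination of the generated system.",
  "equation": {
    "lhs": "v^2*Derivative(u(xi),xi,xi) + s0 - s1*v*Derivative(u(xi),xi) + s2*v^2*Derivative(u(xi),xi)^2 - Derivative(u(xi),xi,xi) - c0 - c1*u(xi) - c2*u(xi)^2 - c3*u(xi)^3",
    "unknown": "u",
    "vars": [
      "xi"
    ],
    "params": [
      "v",
      "s0",
      "s1",
      "s2",
      "c0",
      "c1",
      "c2",
      "c3"
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
    "theta2": "4*a^2*s2*v^2/c3",
    "theta0": "(-c2*s2*v^2/3 + c3*v^2/2 - c3/2 - sqrt(-12*c1*c3*s2^2*v^4 + 4*c2^2*s2^2*v^4 - 9*c3^2*v^4 + 18*c3^2*v^2 - 9*c3^2)/3)/(c3*s2*v^2)",
    "c": "-sqrt(-12*c1*c3*s2^2*v^4 + 4*c2^2*s2^2*v^4 - 9*c3^2*v^4 + 18*c3^2*v^2 - 9*c3^2)/(8*a*s2^2*v^4)",
    "c0": "c1*c2/(3*c3) - c1*sqrt(-12*c1*c3*s2^2*v^4 + 4*c2^2*s2^2*v^4 - 9*c3^2*v^4 + 18*c3^2*v^2 - 9*c3^2)/(9*c3*s2*v^2) - 2*c2^3/(27*c3^2) + c2^2*sqrt(-12*c1*c3*s2^2*v^4 + 4*c2^2*s2^2*v^4 - 9*c3^2*v^4 + 18*c3^2*v^2 - 9*c3^2)/(27*c3^2*s2*v^2) + c3/(4*s2^3) - 3*c3/(4*s2^3*v^2) + 3*c3/(4*s2^3*v^4) - c3/(4*s2^3*v^6) + s0 - sqrt(-12*c1*c3*s2^2*v^4 + 4*c2^2*s2^2*v^4 - 9*c3^2*v^4 + 18*c3^2*v^2 - 9*c3^2)/(12*s2^3*v^2) + sqrt(-12*c1*c3*s2^2*v^4 + 4*c2^2*s2^2*v^4 - 9*c3^2*v^4 + 18*c3^2*v^2 - 9*c3^2)/(6*s2^3*v^4) - sqrt(-12*c1*c3*s2^2*v^4 + 4*c2^2*s2^2*v^4 - 9*c3^2*v^4 + 18*c3^2*v^2 - 9*c3^2)/(12*s2^3*v^6)"
  },
  "remaining": {
    "theta1": "0",
    "s1": "0"
  },
  "branch": 0,
  "conditions": [
    "a*c < 0"
  ],
  "witness": {
    "a": "1",
    "v": "2",
    "s2": "1",
    "c3": "1",
    "c2": "1",
    "c1": "-1",
    "s0": "0",
    "xi0": "0"
  }
}
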