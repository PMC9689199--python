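{
  "id": "rayleigh-bernoulli-k3",
  "tags": [
    "rayleigh",
    "bernoulli"
  ],
  "workflow": "power_series",
  "reference": "Cubic generalized Rayleigh traveling wave, degree-4 ansatz over the Bernoulli equation with k=3 (growing branch).",
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
    "degree": 4,
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
  "parameter_solution": {
    "theta4": "16*b^2*s2*v^2/c3",
    "theta2": "16*a*b*s2*v^2/c3",
    "theta0": "4*a^2*s2*v^2/(3*c3) - c2/(3*c3) + 1/(2*s2) - 1/(2*s2*v^2)",
    "c1": "-16*a^4*s2^2*v^4/(3*c3) + c2^2/(3*c3) - 3*c3/(4*s2^2) + 3*c3/(2*s2^2*v^2) - 3*c3/(4*s2^2*v^4)",
    "c0": "128*a^6*s2^3*v^6/(27*c3^2) - 16*a^4*c2*s2^2*v^4/(9*c3^2) + c2^3/(27*c3^2) - c2/(4*s2^2) + c2/(2*s2^2*v^2) - c2/(4*s2^2*v^4) + c3/(4*s2^3) - 3*c3/(4*s2^3*v^2) + 3*c3/(4*s2^3*v^4) - c3/(4*s2^3*v^6) + s0"
  },
  "remaining": {
    "theta1": "0",
    "theta3": "0",
    "s1": "0"
  },
  "branch": 0,
  "conditions": [
    "b < 0",
    "a > 0"
  ],
  "witness": {
    "a": "1",
    "b": "-1",
    "v": "2",
    "s2": "1",
    "c2": "1",
    "c3": "1",
    "s0": "0",
    "xi0": "0"
  }
}
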