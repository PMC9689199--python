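{
  "id": "fisher-class-L4",
  "tags": [
    "bernoulli",
    "reaction-diffusion"
  ],
  "workflow": "power_series",
  "reference": "Degree-4 ansatz over the Bernoulli equation with k=3 for the quadratic reaction-diffusion ODE (degree 3 is inadmissible: the balance gives a non-integer Bernoulli exponent).",
  "equation": {
    "lhs": "nu1*Derivative(Q(xi),xi,xi) + nu2*Derivative(Q(xi),xi) + mu2*Q(xi)^2 + mu1*Q(xi)",
    "unknown": "Q",
    "vars": [
      "xi"
    ],
    "params": [
      "nu1",
      "nu2",
      "mu1",
      "mu2"
    ]
  },
  "ansatz": {
    "degree": 4,
    "coeff": "a"
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
    "a0": "6*nu2^2/(25*nu1*mu2)",
    "a1": "0",
    "a2": "0",
    "a3": "0",
    "a4": "-24*nu1*b^2/mu2",
    "mu1": "-6*nu2^2/(25*nu1)"
  },
  "remaining": {
    "a": "-nu2/(10*nu1)"
  },
  "branch": 1,
  "conditions": [
    "b > 0",
    "a < 0"
  ],
  "witness": {
    "nu1": "1",
    "nu2": "1",
    "mu2": "1",
    "b": "1",
    "xi0": "0"
  }
}
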