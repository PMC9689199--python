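{
  "id": "fisher-class-L2",
  "tags": ["bernoulli", "reaction-diffusion"],
  "workflow": "power_series",
  "reference": "Kink solution of the second-order quadratic reaction-diffusion traveling-wave ODE (Fisher class), degree-2 ansatz over the Bernoulli auxiliary equation with k=2.",
  "equation": {
    "lhs": "nu1*Derivative(Q(xi),xi,xi) + nu2*Derivative(Q(xi),xi) + mu2*Q(xi)^2 + mu1*Q(xi)",
    "unknown": "Q",
    "vars": ["xi"],
    "params": ["nu1", "nu2", "mu1", "mu2"]
  },
  "ansatz": {"degree": 2, "coeff": "a"},
  "simple_equation": {"family": "bernoulli", "params": {"a": "a", "b": "b", "k": 2}},
  "parameter_solution": {
    "a0": "6*nu2^2/(25*nu1*mu2)",
    "a1": "0",
    "a2": "-6*nu1*b^2/mu2",
    "mu1": "-6*nu2^2/(25*nu1)"
  },
  "remaining": {"a": "-nu2/(5*nu1)"},
  "branch": 0,
  "conditions": ["b < 0", "a > 0"],
  "reproduce": true,
  "solve_for": ["a0", "a1", "a2", "a", "mu1"],
  "hints": {"a1": "0"}
}
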