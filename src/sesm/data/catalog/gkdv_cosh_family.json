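{
  "id": "gkdv-cosh-family",
  "tags": [
    "kdv",
    "composite"
  ],
  "workflow": "gkdv",
  "reference": "Solitary cosh-power wave of the generalized KdV equation with quadratic advection (p=2, A=3), from the composite-function chain.",
  "equation": {
    "lhs": "Derivative(u(x,t),t) + 3*u(x,t)^2*Derivative(u(x,t),x) + Derivative(u(x,t),x,x,x)",
    "unknown": "u",
    "vars": [
      "x",
      "t"
    ],
    "params": []
  },
  "gkdv": {
    "p": 2,
    "A": 3,
    "b1": 1,
    "Omega": 2
  }
}
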