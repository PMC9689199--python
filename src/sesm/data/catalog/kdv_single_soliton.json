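{
  "id": "kdv-single-soliton",
  "tags": [
    "kdv",
    "composite"
  ],
  "workflow": "gkdv",
  "reference": "Single-soliton solution of the classical KdV equation obtained from the generalized-KdV composite chain with p=1, A=-6, b1=1, Omega=-2.",
  "equation": {
    "lhs": "Derivative(u(x,t),t) - 6*u(x,t)*Derivative(u(x,t),x) + Derivative(u(x,t),x,x,x)",
    "unknown": "u",
    "vars": [
      "x",
      "t"
    ],
    "params": []
  },
  "gkdv": {
    "p": 1,
    "A": -6,
    "b1": 1,
    "Omega": -2,
    "expected_mu": "1",
    "expected_nu": "-4"
  }
}
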