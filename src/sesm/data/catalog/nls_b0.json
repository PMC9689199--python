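{
  "id": "nls-b0",
  "tags": [
    "nls",
    "two-simple-equations"
  ],
  "workflow": "explicit",
  "reference": "Bright envelope wave of the nonlinear Schroedinger equation with inverse-quartic modulus nonlinearity (B=0 member of the family solved with two auxiliary equations); amplitude, width and frequency re-derived from the integrated amplitude ODE. Synthetic numeric instance: a=1, b_{-2}=-1, b_0=1/2, kappa=1/3.",
  "equation": {
    "lhs": "I*Derivative(q(x,t),t) + Derivative(q(x,t),x,x) - q(x,t)/Abs(q(x,t))^4 + q(x,t)/2",
    "unknown": "q",
    "vars": [
      "x",
      "t"
    ],
    "params": []
  },
  "solution": "cosh(2*x - 4*t/3)^(1/2) * exp(I*(x/3 + 25*t/18))",
  "witness": {},
  "numeric_only": true
}
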