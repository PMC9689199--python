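{
  "id": "sine-gordon-type-kink",
  "tags": [
    "sine-gordon",
    "product-ansatz"
  ],
  "workflow": "explicit",
  "reference": "Arctan-exponential standing-wave solution of the squared-second-derivative sine-Gordon-type equation, built from a separable product of two exponential auxiliary solutions.",
  "equation": {
    "lhs": "b*Derivative(u(x,t),x,x)^2 + d*Derivative(u(x,t),t,t)^2 - l*sin(u(x,t))^2",
    "unknown": "u",
    "vars": [
      "x",
      "t"
    ],
    "params": [
      "b",
      "d",
      "l",
      "A",
      "alpha",
      "gamma",
      "v"
    ]
  },
  "solution": "4*arctan(A*exp(alpha*((l - d*gamma^4*v^2)^(1/2)/(b^(1/2)*alpha^2))^(1/2)*x + gamma*v^(1/2)*t))",
  "witness": {
    "b": "1",
    "d": "2",
    "l": "3",
    "alpha": "1",
    "gamma": "1",
    "v": "1/2",
    "A": "2"
  },
  "conditions": [
    "l - d*gamma^4*v^2 > 0",
    "b > 0",
    "v > 0"
  ]
}
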