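{
  "lhs": "nu1*Derivative(Q(xi),xi,xi) + nu2*Derivative(Q(xi),xi) + mu2*Q(xi)^2 + mu1*Q(xi)",
  "unknown": "Q",
  "vars": ["xi"],
  "params": ["nu1", "nu2", "mu1", "mu2"]
}
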