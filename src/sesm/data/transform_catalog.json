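{
  "description": "Step-1 transformations converting non-polynomial nonlinearities N(u) into polynomial nonlinearities of F, via u = T(F). 'pattern' names the nonlinearity (and any integer power of it); 'forward' is T, 'inverse' is T^-1. Branch conventions: arctan/artanh principal branches; solution conditions must carry the branch restriction and exclude zeros of the clearing factor.",
  "cases": [
    {"id": 1, "pattern": "exp", "forward": "log(F)", "inverse": "exp(u)"},
    {"id": 2, "pattern": "sin", "forward": "4*arctan(F)", "inverse": "tan(u/4)"},
    {"id": 3, "pattern": "cos", "forward": "4*arctan(F)", "inverse": "tan(u/4)"},
    {"id": 4, "pattern": "tan", "forward": "arctan(F)", "inverse": "tan(u)"},
    {"id": 5, "pattern": "cot", "forward": "arccot(F)", "inverse": "cot(u)"},
    {"id": 6, "pattern": "sinh", "forward": "4*artanh(F)", "inverse": "tanh(u/4)"},
    {"id": 7, "pattern": "cosh", "forward": "4*artanh(F)", "inverse": "tanh(u/4)"},
    {"id": 8, "pattern": "tanh", "forward": "artanh(F)", "inverse": "tanh(u)"},
    {"id": 9, "pattern": "coth", "forward": "arcoth(F)", "inverse": "coth(u)"},
    {"id": 10, "pattern": "sin_or_cos_of_multiple", "forward": "4*arctan(F)", "inverse": "tan(u/4)"}
  ]
}
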