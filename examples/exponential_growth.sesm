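; quadratic reaction-diffusion traveling-wave kink, grammar example
6*nu2^2/(25*nu1*mu2) - 6*nu1*b^2/mu2 * (a*exp(a*(xi+xi0))/(1 - b*exp(a*(xi+xi0))))^2
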