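# S3 — selection through a heritable covariable only: SEP raises testing
# probability (c_sep) and also affects the exposure (delta) and infection
# (a_sep), so SEP variants enter the exposure instrument set and carry
# outcome effects that do not pass through the exposure.  Univariable IVW is
# biased; multivariable MR adjusting for the SEP trait moves the estimate
# back toward the truth.
name: S3
seed: 0
n: 20000
m: 100
theta: 0.3
theta_sev: 0.3
a0: -1.0
a_sep: 0.3
delta_sep_exposure: 0.45
c_sep: 2.0
releases:
  - {tag: r6, fraction: 1.0, c0: 1.0}
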