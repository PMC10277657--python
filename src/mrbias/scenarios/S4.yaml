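# S4 — selection pressure changing over time: four cumulative releases with
# a testing policy that starts highly selective (low intercept, so who gets
# tested is driven by exposure/severity/SEP) and approaches universal
# testing by the final release.  Signature: the reverse-direction estimate
# is non-null at the earliest release only.
name: S4
seed: 0
n: 20000
m: 100
theta: 0.3
theta_sev: 0.3
a0: -1.0
a_sep: 0.3
c_exposure: 1.5
c_severity: 1.5
c_sep: 0.5
releases:
  - {tag: r3, fraction: 0.25, c0: -2.0}
  - {tag: r4, fraction: 0.50, c0: 0.0}
  - {tag: r5, fraction: 0.75, c0: 1.5}
  - {tag: r6, fraction: 1.00, c0: 3.0}
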