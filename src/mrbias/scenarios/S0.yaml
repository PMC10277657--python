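# S0 — null scenario: no selection into testing, near-universal testing
# (minimal misclassification), no pleiotropy, no SEP confounding.
# Used for estimator calibration and false-positive-rate properties.
name: S0
seed: 0
n: 20000
m: 100
theta: 0.3
theta_sev: 0.3
a0: -1.0
releases:
  - {tag: r6, fraction: 1.0, c0: 3.0}
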