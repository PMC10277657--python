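# S2 — pure misclassification: testing is random (no selection terms) but
# incomplete, so population-control schemes label untested infected
# individuals as controls.  contamination_levels lowers the testing
# intercept to raise the contaminated fraction; the population-control
# estimate attenuates monotonically while tested-control schemes do not.
name: S2
seed: 0
n: 20000
m: 100
theta: 0.6
theta_sev: 0.3
a0: -1.0
releases:
  - {tag: r6, fraction: 1.0, c0: 3.0}
contamination_levels: [3.0, 1.0, -0.5]
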