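# S5 — direct summary-level LDSC validation: two traits with known
# heritabilities and genetic correlation, explicit variable LD scores.
kind: ldsc_summary
name: S5
h2_trait1: 0.5
h2_trait2: 0.4
rg: 0.3
M: 5000
N1: 50000
N2: 50000
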