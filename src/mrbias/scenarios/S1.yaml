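# S1 — collider selection into testing: exposure, symptom severity and SEP
# all raise the probability of being tested, and only a minority are tested.
# Signature: reverse-direction (no-relevance) MR departs from the null and
# disease GWAS become genetically correlated with the SEP trait.
name: S1
seed: 0
n: 20000
m: 100
theta: 0.3
theta_sev: 0.3
a0: -1.0
a_sep: 0.3
c_exposure: 1.5
c_severity: 1.5
c_sep: 0.75
releases:
  - {tag: r6, fraction: 1.0, c0: -1.0}
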