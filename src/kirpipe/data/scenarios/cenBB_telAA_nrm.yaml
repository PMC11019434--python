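# Planted-effect scenario: donors homozygous cen B/B - tel A/A (~4.7% of
# the cohort) carry a reduced cause-specific non-relapse-mortality hazard
# (HR 0.65), the association reported for this diplotype; relapse is
# unaffected.  Used by the classify-then-Cox recovery harness.
base: cohort2013
name: cenBB_telAA_nrm
planted_effects:
  - group: {cen: BB, tel: AA}
    hr_relapse: 1.0
    hr_nrm: 0.65
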