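# Planted-effect scenario: donors with the rare cen B01/B01 - tel A/A
# diplotype (~0.6% of the cohort at the default B01 fraction) carry a
# strongly reduced non-relapse-mortality hazard (HR 0.40); relapse is
# unaffected.  Exercises recovery of an effect in a very small group.
base: cohort2013
name: cenB01B01_telAA_nrm
planted_effects:
  - group: {cen_subtype: B01B01, tel: AA}
    hr_relapse: 1.0
    hr_nrm: 0.40
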