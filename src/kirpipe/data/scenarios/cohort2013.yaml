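# Baseline synthetic registry cohort.
#
# Frequencies and outcome anchors follow the published marginal structure
# of a large unrelated-donor alloHCT cohort (AML/MDS, transplanted
# 2013-2018): the 3x3 homozygous/heterozygous cen x tel diplotype table,
# an unclassifiable-genotype fraction, patient C1/C2 and Bw ligand
# frequencies, and constant cause-specific hazards calibrated so the
# 2-year outcome probabilities are 51% EFS, 29% relapse incidence and
# 20% non-relapse mortality under administrative censoring.
name: cohort2013
n: 5017
horizon_years: 5.0
censoring_rate_per_year: 0.0

anchors:
  efs: 0.51
  cif_relapse: 0.29
  cif_nrm: 0.20
  at_years: 2.0

# cen class (rows) x tel class (columns) cell counts; used as sampling
# weights together with the unclassifiable count.
diplotype_counts:
  AA: {AA: 1616, AB: 709, BB: 71}
  AB: {AA: 1170, AB: 809, BB: 109}
  BB: {AA: 237, AB: 211, BB: 43}
unclassifiable_count: 42

# Probability that a centromeric B motif is the B01 subtype (vs B02).
# 0.35 reproduces the observed ~1:7 ratio of B01/B01 to all cen B/B
# genotypes (0.35^2 ~ 29/237).
cen_b01_fraction: 0.35

ligand_freqs: {C1C1: 0.372, C1C2: 0.478, C2C2: 0.150}
bw_freqs: {Bw4-80I: 0.38, Bw4-80T: 0.25, Bw6-only: 0.37}

covariates:
  patient_age: {type: normal, mean: 54.0, sd: 12.0, min: 18.0, max: 81.0}
  donor_age: {type: normal, mean: 30.0, sd: 8.0, min: 18.0, max: 61.0}
  registry: {type: categorical, levels: {EBMT: 0.63, CIBMTR: 0.37}}
  conditioning_mac: {type: bernoulli, p: 0.57}
  female_to_male: {type: bernoulli, p: 0.30}

planted_effects: []
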