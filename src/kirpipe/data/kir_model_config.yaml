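# Model parameter tables for the donor-KIR / patient-ligand classifiers.
#
# The clade memberships, expression subtypes, score weights and genotype
# signature gene sets below are RECONSTRUCTED defaults: the original
# parameter sets live in external supplements that are not reprinted
# here.  Replace any section with the published values for a faithful
# reproduction; analysis reports record this file's checksum so runs are
# attributable to a specific parameterization.
version: 1
provenance: reconstructed defaults; user-replaceable

# Phylogenetic clade membership of KIR2DL1 and KIR2DL3 alleles
# (placeholder allele lists).
clades:
  2DL1:
    clade1: ["2DL1*001", "2DL1*002"]
    clade2: ["2DL1*003", "2DL1*008"]
    clade3: ["2DL1*004", "2DL1*007", "2DL1*010"]
  2DL3:
    clade1: ["2DL3*001", "2DL3*002"]
    clade2: ["2DL3*005", "2DL3*009"]

# KIR3DL1 allotype expression subtypes (high/low surface expression or
# unexpressed "null" allotypes).
kir3dl1_subtypes:
  high: ["3DL1*001", "3DL1*002", "3DL1*008", "3DL1*015", "3DL1*020"]
  low: ["3DL1*005", "3DL1*007"]
  "null": ["3DL1*004"]

# KIR3DL1/HLA-B inhibition strength: expression subtype x patient Bw
# status.  Any pairing with Bw6-only, a null allotype or an absent
# receptor is non-inhibiting.
kir3dl1_inhibition:
  high: {Bw4-80I: strong, Bw4-80T: weak, Bw6-only: non}
  low: {Bw4-80I: weak, Bw4-80T: weak, Bw6-only: non}
  "null": {Bw4-80I: non, Bw4-80T: non, Bw6-only: non}
  absent: non

# Receptor-ligand pairs counted by the functional inhibitory-KIR count
# (receptor present AND cognate patient ligand present).
functional_ikir:
  - {gene: 2DL1, ligand: C2}
  - {gene: 2DL2, ligand: C1}
  - {gene: 2DL3, ligand: C1}
  - {gene: 3DL1, ligand: Bw4}

# Weighted score families.  Each score is a sum over terms of
# weight x indicator(state), where state is one of:
#   ligand_present   - receptor present and cognate ligand present
#   ligand_missing   - receptor present and cognate ligand absent
#   receptor_missing - receptor absent and cognate ligand present
scores:
  inhibitory_score:
    - {gene: 2DL1, ligand: C2, state: ligand_present, weight: 1.0}
    - {gene: 2DL2, ligand: C1, state: ligand_present, weight: 1.0}
    - {gene: 2DL3, ligand: C1, state: ligand_present, weight: 0.75}
    - {gene: 3DL1, ligand: Bw4, state: ligand_present, weight: 1.0}
  missing_kir_score:
    - {gene: 2DL1, ligand: C2, state: ligand_missing, weight: 1.0}
    - {gene: 2DL2, ligand: C1, state: ligand_missing, weight: 1.0}
    - {gene: 2DL3, ligand: C1, state: ligand_missing, weight: 1.0}
    - {gene: 3DL1, ligand: Bw4, state: ligand_missing, weight: 1.0}
  inhibitory_kir_score:
    - {gene: 2DL1, ligand: C2, state: ligand_present, weight: 1.0}
    - {gene: 2DL2, ligand: C1, state: ligand_present, weight: 1.0}
    - {gene: 2DL3, ligand: C1, state: ligand_present, weight: 1.0}
    - {gene: 3DL1, ligand: Bw4, state: ligand_present, weight: 1.0}
  activating_kir_score:
    - {gene: 2DS1, ligand: C2, state: ligand_present, weight: 1.0}
    - {gene: 2DS2, ligand: C1, state: ligand_present, weight: 1.0}
    - {gene: 3DS1, ligand: Bw4, state: ligand_present, weight: 1.0}
  weighted_kir_score:
    - {gene: 2DS1, ligand: C2, state: ligand_present, weight: 1.0}
    - {gene: 2DS2, ligand: C1, state: ligand_present, weight: 1.0}
    - {gene: 3DS1, ligand: Bw4, state: ligand_present, weight: 1.0}
    - {gene: 2DL1, ligand: C2, state: ligand_present, weight: -1.0}
    - {gene: 2DL2, ligand: C1, state: ligand_present, weight: -1.0}
    - {gene: 2DL3, ligand: C1, state: ligand_present, weight: -1.0}
    - {gene: 3DL1, ligand: Bw4, state: ligand_present, weight: -1.0}
  im_kir_score:
    - {gene: 2DL1, ligand: C2, state: ligand_present, weight: 1.0}
    - {gene: 2DL2, ligand: C1, state: ligand_present, weight: 1.0}
    - {gene: 2DL3, ligand: C1, state: ligand_present, weight: 1.0}
    - {gene: 3DL1, ligand: Bw4, state: ligand_present, weight: 1.0}
    - {gene: 2DL1, ligand: C2, state: ligand_missing, weight: 1.0}
    - {gene: 2DL2, ligand: C1, state: ligand_missing, weight: 1.0}
    - {gene: 2DL3, ligand: C1, state: ligand_missing, weight: 1.0}
    - {gene: 3DL1, ligand: Bw4, state: ligand_missing, weight: 1.0}

# Named genotype signatures: conjunctions of gene presence/absence
# conditions, each with the patient subset in which it is analyzed
# (the subset filter is applied by the analysis pipeline, not here).
signatures:
  G2:
    present: [2DS2, 2DL2]
    absent: [2DS3]
    subset: C1C1
  G3:
    present: [3DS1, 2DS1]
    absent: []
    subset: Bw4
  G5:
    present: [2DS1, 2DS2]
    absent: [2DL3]
    subset: null
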