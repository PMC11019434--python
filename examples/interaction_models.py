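"""Evaluate the donor-KIR / patient-ligand classifiers for one pair.

Shows the KIR2DS1 and KIR3DL1 groupings, phylogenetic clade presence,
the functional inhibitory-KIR count and the weighted KIR-ligand score
family for a donor genotype against a C1/C2, Bw4-80I patient.  All model
parameters come from the shipped (reconstructed, user-replaceable)
config; analysis reports record its checksum.
"""

from kirpipe import (
    DonorKirGenotype,
    GeneState,
    GeneStatus,
    KIR_LOCI,
    LigandProfile,
    interaction_profile,
    load_score_config,
)

PRESENT = {"3DL3", "3DP1", "2DL4", "3DL2", "2DL3", "2DP1", "2DL1",
           "3DL1", "2DS4", "3DS1", "2DL5", "2DS5", "2DS1"}
ALLELES = {"2DL1": ("2DL1*003",), "2DL3": ("2DL3*001",), "3DL1": ("3DL1*001",)}

genes = {}
for locus in KIR_LOCI:
    if locus in PRESENT:
        genes[locus] = GeneStatus(GeneState.PRESENT, ALLELES.get(locus, ()))
    else:
        genes[locus] = GeneStatus(GeneState.ABSENT)
donor = DonorKirGenotype("donor-1", genes)

patient = LigandProfile(
    subject_id="patient-1", c_group="C1C2", bw="Bw4-80I", per_allele_epitopes=()
)

cfg = load_score_config()
profile = interaction_profile(donor, patient, cfg)
print(f"model config checksum: {cfg.checksum}\n")
for key, value in profile.items():
    print(f"{key:>24}: {value}")
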