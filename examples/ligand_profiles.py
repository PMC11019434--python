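"""Build patient KIR-ligand profiles and grade a donor-patient HLA match.

HLA-C alleles split into the C1/C2 epitope groups and HLA-B alleles into
Bw4-80I / Bw4-80T / Bw6; the profile summarizes which KIR ligands a
patient encodes.  The match grade counts matched alleles out of 10 over
HLA-A/B/C/DRB1/DQB1 and flags mismatches that change KIR ligands.
"""

from kirpipe import HlaTyping, hla_match_grade, ligand_profile

patient = HlaTyping(
    "patient-1",
    {
        "A": ("A*01:01", "A*02:01"),
        "B": ("B*57:01", "B*07:02"),   # Bw4-80I + Bw6
        "C": ("C*07:01", "C*04:01"),   # C1 + C2
        "DRB1": ("DRB1*03:01", "DRB1*04:01"),
        "DQB1": ("DQB1*02:01", "DQB1*03:02"),
    },
)
donor = HlaTyping(
    "donor-1",
    {**patient.alleles, "C": ("C*07:01", "C*07:02")},  # C-mismatch, C2 -> C1
)

profile = ligand_profile(patient)
print(f"patient C group: {profile.c_group}  (C1+: {profile.c1_positive})")
print(f"patient Bw status: {profile.bw}  (Bw4+: {profile.bw4_positive})")

match = hla_match_grade(donor, patient)
print(f"\nHLA match: {match.grade} ({match.matched}/{match.out_of} alleles)")
print(f"mismatched loci: {match.mismatched_loci}")
print(f"C1-C2 ligand change at HLA-C: {match.c1c2_change}")
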