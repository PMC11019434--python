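"""Recover a planted hazard ratio through the full pipeline.

Generates a synthetic cohort from the shipped scenario in which donors
with the cen B/B - tel A/A diplotype (~5% of donors) carry a reduced
non-relapse-mortality hazard (HR 0.65), classifies every donor genotype
from the gene-level table, and fits the adjusted cause-specific Cox
model.  The recovered HR should approach 0.65 as n grows, while the
relapse HR for the same group stays near 1 (the effect is
cause-specific).  n = 50,000 keeps this demo fast; the acceptance
analysis uses 200,000.
"""

import numpy as np

from kirpipe import coxph_cause_specific, generate_cohort
from kirpipe.pipeline import classify_cohort

cohort = generate_cohort("cenBB_telAA_nrm", seed=11, n=50_000)
labels = classify_cohort(cohort.genotype_table)
df = cohort.records.merge(labels, on="donor_id")
df["flagged"] = ((df.cen_class == "BB") & (df.tel_class == "AA")).astype(int)
print(f"flagged donors: {df.flagged.sum()} ({100 * df.flagged.mean():.1f}%)")

for cause, endpoint in ((2, "NRM"), (1, "relapse")):
    fit = coxph_cause_specific(
        df,
        ["flagged", "patient_age", "donor_age", "female_to_male"],
        cause=cause,
        strata=["registry"],
    )
    row = fit.row("flagged[1]")
    print(
        f"{endpoint:>8}: HR {row['hr']:.3f} "
        f"(95%-CI {row['ci_low']:.3f}-{row['ci_high']:.3f}), p={row['p']:.3f}"
    )
print("planted: NRM HR 0.65, relapse HR 1.0")
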