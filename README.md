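# kirpipe

Donor **KIR genotype classification** and **competing-risks outcome
analysis** for allogeneic hematopoietic cell transplantation (alloHCT)
cohorts — with a synthetic cohort generator so every stage can be
developed and validated without access-restricted registry data.

Natural killer (NK) cell alloreactivity after alloHCT is thought to be
shaped by the donor's Killer-cell Immunoglobulin-like Receptor (*KIR*)
genotype and the patient's HLA-encoded KIR ligands. Registry studies
test this by classifying donors into *KIR* haplotype motifs and
donor–patient receptor–ligand interaction groups, then associating those
classifications with relapse, event-free survival (EFS) and non-relapse
mortality (NRM) under competing risks. `kirpipe` implements that entire
workflow as a reusable library for immunogenetics and transplant-outcomes
researchers.

## What it does

**Genotype classification** (`kirpipe.genotype`). The KIR locus splits
into a centromeric (cen) and a telomeric (tel) motif, each of group *A*
(fixed, mostly inhibitory gene content) or *B* (carrying activating
genes). From per-gene presence/absence calls the classifier assigns the
cen and tel diplotype (A/A, A/B, B/B) by matching gene content against
an editable motif rule table; patterns compatible with no motif pair are
reported unclassifiable, not forced. Centromeric B/B genotypes are
further split into B01/B02 subtypes (B02 lacks the
2DL5–2DS3/5–2DP1–2DL1 block); B01/B01 vs B01/B02 requires copy-number
evidence at *KIR2DL1*. B-motif content maps to the Neutral (0–1 B
motifs) / Better (≥2, no cen B/B) / Best (cen B/B) categories.

**Ligand profiles** (`kirpipe.ligands`). HLA-C alleles group into the
C1/C2 epitopes (ligands of KIR2DL2/3 and KIR2DL1/2DS1), HLA-B alleles
into Bw4-80I / Bw4-80T / Bw6 (Bw4 is the KIR3DL1 ligand). Shipped
two-field lookup tables are user-replaceable; donor–patient HLA match
grades (x/10) are computed with flags for mismatches that change KIR
ligands.

**Interaction models** (`kirpipe.models`). The classifier families used
in donor-KIR association studies: KIR2DL1/2DL3 phylogenetic clade
presence, KIR2DS1 × C1/C2 groups, KIR3DL1 × Bw4 inhibition strength
(strong/weak/non), the functional inhibitory-KIR count, weighted
KIR-ligand scores (missing / inhibitory / activating / weighted /
inhibitory-missing) and named genotype signatures — all parameterized by
an editable config whose checksum is recorded in reports.

**Survival statistics** (`kirpipe.survival`). Kaplan–Meier with
Greenwood variance, the log-rank test, the Aalen–Johansen cumulative
incidence estimator (with S(t) + ΣCIF(t) = 1 exact at every event
time), Gray's K-sample test for cumulative incidence under competing
risks, and stratified cause-specific Cox regression (Efron ties, Wald
inference) where competing events are censored at their time. Cox and
log-rank go through `lifelines`; Aalen–Johansen and Gray's test are
implemented here and cross-checked against the R `cmprsk` reference in
the test suite.

**Synthetic cohorts** (`kirpipe.cohort`). Scenario-driven generation of
cohorts: diplotype frequencies shaped like a published 3×3 cen × tel
table, gene content realized from motif templates (so classification
round-trips exactly), independent ligand and covariate draws, and
competing-risks outcomes from constant cause-specific hazards calibrated
in closed form to 2-year EFS/relapse/NRM anchors — with planted hazard
ratios for parameter-recovery studies.

**Pipeline & CLI** (`kirpipe.pipeline`, `kirpipe` command). Frequency
tables with marginals, per-classifier association tables (three
endpoints: relapse incidence, EFS, NRM), TSV/markdown/JSON reports, and
thin `classify` / `ligands` / `simulate` / `analyze` / `report`
subcommands.

## Worked example

Recover a planted effect through the full pipeline
(`examples/synthetic_recovery.py`): generate 50,000 donor–patient pairs
in which cen B/B – tel A/A donors (~5%) carry an NRM hazard ratio of
0.65, classify every genotype from the gene-level table, and fit the
adjusted cause-specific Cox models:

```
$ python examples/synthetic_recovery.py
flagged donors: 2371 (4.7%)
     NRM: HR 0.635 (95%-CI 0.584-0.692), p=0.000
 relapse: HR 0.967 (95%-CI 0.913-1.024), p=0.248
planted: NRM HR 0.65, relapse HR 1.0
```

The NRM hazard ratio estimated from the classified labels approaches the
planted 0.65 while the relapse hazard for the same donors stays near 1 —
the effect is cause-specific, as planted. The other examples
(`classify_genotypes.py`, `ligand_profiles.py`, `interaction_models.py`,
`competing_risks.py`) each demonstrate one capability in a few lines.

From the shell:

```bash
kirpipe simulate cohort2013 --seed 1 --n 5000 -o out/
kirpipe classify out/genotypes.tsv -o out/labels.tsv
```

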