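# Methods

## Genotype classification model

A KIR haplotype is modeled as an unordered pair of centromeric motifs
plus an unordered pair of telomeric motifs. The shipped rule table
(`kirpipe/data/kir_motif_rules.yaml`) defines three centromeric motifs —
cen-A (2DL3–2DP1–2DL1), cen-B01 (2DS2–2DL2–2DL5–2DS3/5–2DP1–2DL1) and
cen-B02 (2DS2–2DL2) — and two telomeric motifs, tel-A (3DL1–2DS4) and
tel-B (3DS1–2DL5–2DS3/5–2DS1). Classification is *compatibility
matching*: a presence/absence vector over the 16 loci is compared with
the gene-content union of every motif-pair combination. Genes unique to
one region must match exactly; 2DL5 (carried by both cen-B01 and tel-B)
is matched genome-wide against the number of carrying motif copies; the
2DS3/2DS5 pair is an interchangeable slot (a carrying motif may hold
either gene, so the number of distinct slot genes present must be
between one and the slot count). Framework genes (3DL3, 3DP1, 2DL4,
3DL2) are excluded from matching — their absence marks a genotype
invalid instead of unclassifiable. A vector compatible with no pair is
**unclassifiable**; this is deliberate — registry data contain gene
patterns that no A/B motif combination explains, and forcing them into a
class would bias motif frequencies. Unknown gene states act as
wildcards and block classification only when the compatible combinations
disagree on the class (a "decisive" unknown).

Region classes are assigned per region: the tel class of a genotype with
an aberrant cen pattern is still reported, but the combined B-motif
count and Neutral/Better/Best category are undefined whenever either
region is unclassifiable.

B01/B01 vs B01/B02 cannot be distinguished by presence/absence (both
contain the full B01 gene set), so the subtype is resolved by copy
evidence at 2DL1: in a cen B/B genotype no cen-A contributes 2DL1, hence
two 2DL1 copies (or two distinct alleles) imply B01/B01 and a known
single copy implies B01/B02; a single allele call without copy
information stays *undetermined* rather than guessed. Because the
standard POS/NEG/allele-list table format cannot express "exactly one
copy", the parser accepts an optional `<locus>_cn` integer column; the
synthetic generator emits it so classification round-trips exactly
through the on-disk format.

## Ligand model

Epitope assignment is a pure two-field table lookup, not residue
parsing: the shipped tables cover widely established assignments only
(C1 = Asn80-type HLA-C groups such as C\*01/03/07/08/12/14/16:01,
C2 = Lys80 groups such as C\*02/04/05/06/15/17/18; Bw4-80I e.g.
B\*51:01/53:01/57:01/58:01, Bw4-80T e.g. B\*27:05/44:02/44:03, plus a
Bw6 list). Unlisted alleles fall back to the first-field group only when
every listed two-field allele of that group agrees; otherwise they are
flagged `unknown` and profiles touching them are marked partial and
excluded from classifier regressions with a logged count. Users replace
the tables with a current ligand listing for production use. Null
alleles and rare variants are therefore never silently grouped.

When a typing carries several HLA-B epitopes the profile keeps the
highest-priority Bw4 (80I > 80T); a profile with an unknown B allele and
no observed Bw4-80I is partial, because the unknown allele could carry
the stronger epitope.

## Interaction models

All model parameters — clade membership of 2DL1/2DL3 alleles, 3DL1
expression subtypes (high/low/null) and the subtype × Bw decision table,
weights of the five score families, and the G2/G3/G5 signature gene
sets — live in `kirpipe/data/kir_model_config.yaml`. The shipped values
are clearly marked **reconstructed placeholders**: the original
parameter sets are external supplementary material not reproduced here,
and faithful replication requires populating the config from those
sources. Every analysis records the config checksum. The score engine is
generic: a score is Σ weight × indicator over (receptor, ligand, state)
terms with states *ligand-present* (receptor and cognate ligand both
present), *ligand-missing* (receptor without its ligand) and
*receptor-missing* (ligand without its receptor). With unit weights on
the four canonical inhibitory pairs (2DL1–C2, 2DL2–C1, 2DL3–C1,
3DL1–Bw4) the inhibitory sum reproduces the functional iKIR count, which
the tests assert. With two 3DL1 alleles the higher-expression allotype
determines the inhibition class (inhibition needs one expressed copy).
Continuous scores enter regression unscaled (per-unit hazard ratios);
standardization is an opt-in flag.

## Survival statistics

Event coding: `cause` 0 = censored, 1 = relapse/progression, 2 =
non-relapse death; times in months. EFS is the composite of any
non-censored cause.

* **Kaplan–Meier** product-limit with Greenwood variance, simultaneous
  handling of tied failures.
* **Aalen–Johansen**: CIF increments S(t−)·d_k(t)/Y(t) built from the
  same product-limit overall survival, so S + ΣCIF = 1 holds to machine
  precision at every event time (the package implements KM/AJ itself for
  exactly this reason; `lifelines`' AJ jitters ties). The variance is
  the standard counting-process delta-method estimator; tests check
  estimates to ~1e-7 and variances to ~10% against R `cmprsk`.
* **Gray's K-sample test** (ρ = 0 weights) compares subdistribution
  hazards with modified risk sets R_j(t) = Y_j(t)(1−F̂_1j(t−))/Ŝ_j(t−).
  The covariance of the score vector is assembled from the martingale
  representation, including the correction terms induced by estimating
  F and S inside the risk sets (coefficients K·e_jl − B_jl·F̂_other/Y on
  cause-1 jumps and −B_jl·(1−F̂_1)/Y on competing jumps, with B_jl the
  reverse-time integral of K·e_jl·(Y_l/Ŝ_l)dΛ̂_1). This estimator is
  asymptotically equivalent to, but not a port of, the reference
  implementation; under the null the two agree closely (test tolerance
  15% on the statistic, 0.02 on p) and the type-I error is 4–6% at
  α = 0.05 over 2000 replicates. A 10,000-draw permutation oracle bounds
  the chi-square p within ±0.02 on a small fixture.
* **Cause-specific Cox** regression delegates to `lifelines.CoxPHFitter`
  (Efron tie correction, per-stratum risk sets); competing causes are
  censored at their event time. Estimates match brute-force maximization
  of the Efron partial likelihood to 1e-4 on a tied fixture. Wald 95%
  CIs use the 1.96 normal quantile and two-sided Wald p-values are
  reported. Only Efron tie handling is offered (the backend implements
  no alternative; with month-granular, heavily tied registry data Efron
  is the appropriate choice anyway). Categorical covariates are
  dummy-coded against their first (or declared) level with missing
  values as an explicit `missing` category; rows missing a continuous
  covariate are dropped with a logged count; exactly collinear or
  constant design columns raise an error naming them. No
  multiple-testing adjustment is applied anywhere, and the analysis
  logs that fact; this mirrors the exploratory reporting convention the
  pipeline reproduces.

## Synthetic cohort model

The generator's defaults are the study conditions, not tuning knobs:

* **Diplotype frequencies**: the nine cen × tel cell counts
  1616/709/71/1170/809/109/237/211/43 plus 42 unclassifiable in 5017 —
  the published 3×3 table — used as multinomial weights.
* **B01 fraction 0.35**: the probability that a centromeric B motif is
  B01, chosen once so that P(B01/B01 | cen B/B) = 0.35² ≈ 29/237 matches
  the printed subgroup sizes; it puts the cen B01/B01–tel A/A group at
  ~0.6% of the cohort.
* **Outcome model**: constant cause-specific hazards solved in closed
  form from the 2-year anchors (EFS 51%, relapse 29%, NRM 20%):
  λ_total = −ln(0.51)/2 ≈ 0.3366/yr, λ_rel = λ_total·29/49 ≈ 0.199/yr,
  λ_nrm ≈ 0.137/yr, with administrative censoring at 5 years (optional
  exponential censoring off by default). Constant hazards are the
  simplest model consistent with point anchors; a Weibull shape is a
  possible extension, not implemented.
* **Ligand frequencies** C1C1/C1C2/C2C2 = 0.372/0.478/0.150 and Bw4+ =
  0.63 (split 0.38/0.25 between 80I and 80T) follow the published group
  sizes; ligands, diplotypes and covariates are drawn independently —
  correct for unrelated donors (donor KIR ⟂ patient HLA) but a
  simplification for covariates.
* **Covariates** are sampling noise by construction (no effect on
  hazards): patient age ~ N(54, 12²) clipped to 18–81, donor age ~
  N(30, 8²) clipped to 18–61, registry EBMT/CIBMTR 0.63/0.37,
  myeloablative conditioning 0.57, female-to-male 0.30. Adjusted models
  on synthetic data therefore test that adjustment does not distort the
  planted effect, not confounding control.

What the generator deliberately does **not** emulate: linkage
disequilibrium between KIR loci beyond the motif templates, allele
frequencies (allele pools are uniform), covariate–outcome and
covariate–covariate dependence, non-constant hazards, and GVHD outcomes.
Passing recovery tests therefore show the pipeline is unbiased under the
declared model, not that real-data effects of this size are detectable
against real confounding.

Planted effects multiply one cause-specific hazard for donors matching a
label pattern (e.g. cen B/B ∧ tel A/A → NRM hazard × 0.65, or
cen B01/B01 ∧ tel A/A → × 0.40, the two shipped scenarios). Recovery at
n = 200,000 with ~5% (resp. ~0.6%) prevalence has a Wald SE of roughly
0.02 (resp. 0.03) on the HR scale, so the ±0.05 / ±0.10 test tolerances
are ~2.5–3σ. Generation uses `numpy.random.default_rng` (PCG64); a
(scenario, seed) pair is bit-reproducible.

## Pipeline conventions

* EFS event = first of relapse/progression or death from any cause.
* Percentages round half-up to one decimal (the convention of printed
  frequency tables); the classified total is the denominator.
* Frequency tables report the double-homozygous count (four corner
  cells) and the either-homozygous count (classified total minus the
  center A/B–A/B cell).
* Classifier levels `unknown` / `unclassifiable` / `undetermined` are
  excluded from regressions with logged counts, never imputed.
* Reference levels carry HR 1 with an empty CI; swapping the reference
  inverts the HR (asserted in tests).
* Reports embed run metadata (seeds, config checksums, row counts);
  outputs are `associations.tsv`, `frequencies.tsv`, `report.md`,
  `run.json`.

## Problem sizes in tests and the acceptance script

Calibration checks use n = 100,000 (Monte-Carlo SE ≈ 0.16 percentage
points at the anchors, against ±1-point tolerances); recovery checks use
n = 200,000; test calibration uses 2000 null replicates of n = 150; the
permutation oracle uses 10,000 draws on 60 records. These sizes make the
stochastic tolerances comfortable multiples of the Monte-Carlo error
while keeping a full run to a few minutes.

## Known limitations

* The shipped clade, 3DL1-subtype, score-weight and signature tables are
  reconstructed placeholders (see above); conclusions about those
  specific models require user-supplied parameters.
* Epitope tables are partial; coverage gaps surface as `unknown`, never
  as a guess.
* No haplotype phasing or haplotype-frequency estimation (EM-based
  ambiguity resolution is out of scope); gene-content classification
  only.
* No Fine–Gray subdistribution regression, time-varying covariates or
  frailty terms; Gray's test is used only for univariable CIF
  comparisons, cause-specific Cox for everything adjusted.
* 2DL5 is one locus unless the input distinguishes 2DL5A/2DL5B; the
  2DS3/2DS5 slot is interchangeable by design.
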