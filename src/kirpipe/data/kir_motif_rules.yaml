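# Centromeric/telomeric KIR haplotype motif rule table.
#
# This file is data, not code: it defines the marker genes and the full
# motif -> gene-content compatibility matrix used to assign cen/tel A/B
# diplotype classes from per-locus presence/absence calls.  Edit or replace
# it to use alternative haplotype definitions.
#
# Motif gene contents follow the common-haplotype structure of the human
# KIR locus: cen-A carries 2DL3 (plus the 2DP1-2DL1 block), cen-B carries
# 2DS2-2DL2, with the B01 subtype additionally carrying the
# 2DL5-2DS3/5-2DP1-2DL1 block that the B02 subtype lacks; tel-A carries
# 3DL1 and 2DS4, tel-B carries 3DS1-2DL5-2DS3/5-2DS1.  Framework genes
# (3DL3, 3DP1, 2DL4, 3DL2) are present on every haplotype and are excluded
# from compatibility matching (their absence flags the genotype invalid
# instead).
version: 1
framework_genes: [3DL3, 3DP1, 2DL4, 3DL2]

# Genes that occur in motifs of both regions.  Presence/absence typing
# cannot attribute them to one region, so they are matched genome-wide
# against the summed expectation of the four motif copies.
shared_genes: [2DL5]

# Interchangeable gene slots: a motif carrying the slot may carry either
# member gene.  Matched genome-wide like shared genes, by slot count.
slots:
  - name: 2DS3/5
    genes: [2DS3, 2DS5]

regions:
  cen:
    a_motifs: [cenA]
    b_motifs: [cenB01, cenB02]
    # quick marker summary (informational; classification uses the matrix)
    marker_genes:
      A: [2DL3]
      B: [2DL2, 2DS2]
  tel:
    a_motifs: [telA]
    b_motifs: [telB]
    marker_genes:
      A: [3DL1, 2DS4]
      B: [3DS1, 2DS1]

motifs:
  cenA:
    region: cen
    type: A
    genes: [2DL3, 2DP1, 2DL1]
  cenB01:
    region: cen
    type: B
    subtype: B01
    genes: [2DS2, 2DL2, 2DL5, 2DS3/5, 2DP1, 2DL1]
  cenB02:
    region: cen
    type: B
    subtype: B02
    genes: [2DS2, 2DL2]
  telA:
    region: tel
    type: A
    genes: [3DL1, 2DS4]
  telB:
    region: tel
    type: B
    genes: [3DS1, 2DL5, 2DS3/5, 2DS1]
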