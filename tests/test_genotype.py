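"""Genotype parsing and cen/tel haplotype-motif classification."""

from __future__ import annotations

import io

import pytest
from hypothesis import given, settings, strategies as st

from kirpipe.genotype import (
    CenBSubtype,
    CooleyCategory,
    DonorKirGenotype,
    FRAMEWORK_GENES,
    GeneState,
    GeneStatus,
    GenotypeClass,
    KIR_LOCI,
    assign_cen_b_subtype,
    assign_region_genotype,
    classify_diplotype,
    parse_genotype_table,
)
from conftest import CEN_A, CEN_B01, CEN_B02, FW, TEL_A, TEL_B, make_genotype


class TestParsing:
    def _table(self, rows: list[str], extra_cols: str = "") -> io.StringIO:
        header = "donor_id\t" + "\t".join(KIR_LOCI) + extra_cols
        return io.StringIO("\n".join([header] + rows))

    def test_pos_neg_and_allele_cells(self):
        cells = ["POS"] * len(KIR_LOCI)
        cells[KIR_LOCI.index("2DL3")] = "NEG"
        cells[KIR_LOCI.index("2DL1")] = "001+003"
        gs = parse_genotype_table(self._table(["D1\t" + "\t".join(cells)]))
        (g,) = gs
        assert g.state("2DL3") is GeneState.ABSENT
        assert g.state("2DS2") is GeneState.PRESENT
        assert g.status("2DL1").alleles == ("2DL1*001", "2DL1*003")
        # two distinct alleles imply at least two copies
        assert g.status("2DL1").copy_number == 2

    def test_empty_cell_is_unknown_and_empty_file_ok(self):
        cells = [""] + ["POS"] * (len(KIR_LOCI) - 1)
        gs = parse_genotype_table(self._table(["D1\t" + "\t".join(cells)]))
        assert gs[0].state("3DL3") is GeneState.UNKNOWN
        assert parse_genotype_table(self._table([])) == []

    def test_missing_locus_column_is_hard_error(self):
        header = "donor_id\t" + "\t".join(l for l in KIR_LOCI if l != "2DS4")
        with pytest.raises(ValueError, match="2DS4"):
            parse_genotype_table(io.StringIO(header + "\nD1\t" + "\t".join(["POS"] * 15)))

    def test_malformed_token_flags_row_and_sets_unknown(self):
        cells = ["POS"] * len(KIR_LOCI)
        cells[KIR_LOCI.index("2DL1")] = "xyz!"
        gs = parse_genotype_table(self._table(["D1\t" + "\t".join(cells)]))
        assert gs[0].state("2DL1") is GeneState.UNKNOWN
        assert any("line 2" in w for w in gs[0].warnings)

    def test_copy_number_column(self):
        cells = ["POS"] * len(KIR_LOCI)
        cells[KIR_LOCI.index("2DL1")] = "003"
        gs = parse_genotype_table(
            self._table(["D1\t" + "\t".join(cells) + "\t1"], extra_cols="\t2DL1_cn")
        )
        assert gs[0].status("2DL1").copy_number == 1

    def test_comma_delimiter_autodetected(self):
        header = "donor_id," + ",".join(KIR_LOCI)
        row = "D1," + ",".join(["POS"] * len(KIR_LOCI))
        gs = parse_genotype_table(io.StringIO(header + "\n" + row))
        assert gs[0].state("2DL1") is GeneState.PRESENT

    def test_framework_gene_absence_flags_invalid(self):
        g = make_genotype(FW - {"3DP1"} | CEN_A | TEL_A)
        assert not g.is_valid
        assert any("3DP1" in w for w in g.warnings)


class TestRegionAssignment:
    @pytest.mark.parametrize(
        "present, region, expected",
        [
            (CEN_A, "cen", GenotypeClass.AA),
            (CEN_A | CEN_B01, "cen", GenotypeClass.AB),
            (CEN_A | CEN_B02, "cen", GenotypeClass.AB),
            (CEN_B01 | CEN_B02, "cen", GenotypeClass.BB),
            (CEN_B02, "cen", GenotypeClass.BB),
            (TEL_A, "tel", GenotypeClass.AA),
            (TEL_A | TEL_B, "tel", GenotypeClass.AB),
            (TEL_B, "tel", GenotypeClass.BB),
        ],
    )
    def test_rule_table_classes(self, present, region, expected):
        other = TEL_A if region == "cen" else CEN_A
        g = make_genotype(FW | present | other)
        assert assign_region_genotype(g, region).genotype_class is expected

    def test_no_marker_genes_is_unclassifiable(self):
        # all of 2DL3, 2DL2, 2DS2 absent matches no cen motif pair
        g = make_genotype(FW | {"2DP1", "2DL1"} | TEL_A)
        assert (
            assign_region_genotype(g, "cen").genotype_class
            is GenotypeClass.UNCLASSIFIABLE
        )

    def test_pattern_outside_compatibility_matrix_is_unclassifiable(self):
        # 2DL2 without 2DS2 is carried by no configured cen motif
        g = make_genotype(FW | {"2DL2"} | TEL_A)
        assert (
            assign_region_genotype(g, "cen").genotype_class
            is GenotypeClass.UNCLASSIFIABLE
        )

    def test_decisive_unknown_blocks_classification(self):
        g = make_genotype(FW | CEN_A | TEL_A, unknown={"2DS2", "2DL2"})
        assert (
            assign_region_genotype(g, "cen").genotype_class
            is GenotypeClass.UNCLASSIFIABLE
        )
        assert any("decisive" in w for w in g.warnings)

    def test_non_decisive_unknown_does_not_block(self):
        g = make_genotype(FW | CEN_A | TEL_A, unknown={"2DP1"})
        assert assign_region_genotype(g, "cen").genotype_class is GenotypeClass.AA

    def test_aberrant_cen_does_not_block_tel(self):
        g = make_genotype(FW | {"2DP1", "2DL1"} | TEL_A)
        assert assign_region_genotype(g, "tel").genotype_class is GenotypeClass.AA


class TestCenBSubtype:
    def test_block_deletion_gives_b02b02(self):
        g = make_genotype(FW | CEN_B02 | TEL_A)
        cen = assign_region_genotype(g, "cen")
        assert assign_cen_b_subtype(g, cen) is CenBSubtype.B02B02

    def test_two_distinct_2dl1_alleles_give_b01b01(self):
        g = make_genotype(
            FW | CEN_B01 | TEL_A, alleles={"2DL1": ("2DL1*004", "2DL1*007")}
        )
        cen = assign_region_genotype(g, "cen")
        assert assign_cen_b_subtype(g, cen) is CenBSubtype.B01B01

    def test_single_copy_gives_b01b02(self):
        g = make_genotype(
            FW | CEN_B01 | CEN_B02 | TEL_A,
            alleles={"2DL1": ("2DL1*003",)},
            copy_numbers={"2DL1": 1},
        )
        cen = assign_region_genotype(g, "cen")
        assert assign_cen_b_subtype(g, cen) is CenBSubtype.B01B02

    def test_single_allele_without_copy_number_is_undetermined(self):
        g = make_genotype(FW | CEN_B01 | TEL_A, alleles={"2DL1": ("2DL1*003",)})
        cen = assign_region_genotype(g, "cen")
        assert assign_cen_b_subtype(g, cen) is CenBSubtype.UNDETERMINED

    def test_non_bb_cen_raises(self):
        g = make_genotype(FW | CEN_A | TEL_A)
        cen = assign_region_genotype(g, "cen")
        with pytest.raises(ValueError, match="cen B/B"):
            assign_cen_b_subtype(g, cen)


class TestDiplotypeClassification:
    @pytest.mark.parametrize(
        "cen, tel, count, category",
        [
            (CEN_B02, TEL_A, 2, CooleyCategory.BEST),
            (CEN_A, TEL_A, 0, CooleyCategory.NEUTRAL),
            (CEN_A | CEN_B01, TEL_A | TEL_B, 2, CooleyCategory.BETTER),
            (CEN_A, TEL_A | TEL_B, 1, CooleyCategory.NEUTRAL),
            (CEN_A, TEL_B, 2, CooleyCategory.BETTER),
        ],
    )
    def test_b_motif_count_and_category(self, cen, tel, count, category):
        cls = classify_diplotype(make_genotype(FW | cen | tel))
        assert cls.b_motif_count == count
        assert cls.cooley_category is category

    def test_best_iff_cen_bb(self):
        cls = classify_diplotype(make_genotype(FW | CEN_B02 | TEL_B))
        assert cls.cooley_category is CooleyCategory.BEST
        assert cls.is_double_homozygous

    def test_unclassifiable_propagates(self):
        cls = classify_diplotype(make_genotype(FW | {"2DL2"} | TEL_A))
        assert cls.cooley_category is CooleyCategory.UNCLASSIFIED
        assert cls.b_motif_count is None
        assert not cls.is_double_homozygous


# ---------------------------------------------------------------------------
# Properties

_MOTIF_SETS_CEN = [CEN_A, CEN_B01, CEN_B02]
_MOTIF_SETS_TEL = [TEL_A, TEL_B]


@st.composite
def random_presence_genotype(draw):
    """An arbitrary presence/absence vector over the 12 non-framework loci."""
    present = set(FRAMEWORK_GENES)
    for locus in KIR_LOCI:
        if locus not in present and draw(st.booleans()):
            present.add(locus)
    return make_genotype(present)


class TestProperties:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(random_presence_genotype())
    def test_totality_and_determinism(self, g):
        """Every 16-gene vector maps to exactly one (cen, tel) class pair."""
        first = classify_diplotype(g)
        second = classify_diplotype(
            DonorKirGenotype(g.donor_id, dict(reversed(list(g.genes.items()))))
        )
        assert first.cen.genotype_class is second.cen.genotype_class
        assert first.tel.genotype_class is second.tel.genotype_class
        assert first.cen.genotype_class in GenotypeClass
        assert first.tel.genotype_class in GenotypeClass

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(random_presence_genotype())
    def test_category_consistency(self, g):
        """Cooley category follows the B-motif count and cen class."""
        cls = classify_diplotype(g)
        if cls.cooley_category is CooleyCategory.UNCLASSIFIED:
            assert cls.b_motif_count is None
        elif cls.cen.genotype_class is GenotypeClass.BB:
            assert cls.cooley_category is CooleyCategory.BEST
            assert cls.b_motif_count >= 2
        elif cls.b_motif_count >= 2:
            assert cls.cooley_category is CooleyCategory.BETTER
        else:
            assert cls.cooley_category is CooleyCategory.NEUTRAL

    def test_partition_over_cohort(self):
        """Category counts partition any cohort; Best count = cen B/B count."""
        import numpy as np

        rng = np.random.default_rng(5)
        genotypes = []
        for _ in range(300):
            cen = _MOTIF_SETS_CEN[rng.integers(3)] | _MOTIF_SETS_CEN[rng.integers(3)]
            tel = _MOTIF_SETS_TEL[rng.integers(2)] | _MOTIF_SETS_TEL[rng.integers(2)]
            genotypes.append(make_genotype(FW | cen | tel))
        classes = [classify_diplotype(g) for g in genotypes]
        from collections import Counter

        counts = Counter(c.cooley_category for c in classes)
        assert sum(counts.values()) == len(genotypes)
        n_cen_bb = sum(c.cen.genotype_class is GenotypeClass.BB for c in classes)
        assert counts[CooleyCategory.BEST] == n_cen_bb

    def test_subtype_monotonic_under_2dl1_removal(self):
        """Dropping 2DL1 from a B01-containing cen B/B never moves the
        subtype toward B01-richer classes."""
        order = {
            CenBSubtype.B01B01: 2,
            CenBSubtype.B01B02: 1,
            CenBSubtype.UNDETERMINED: 1,
            CenBSubtype.B02B02: 0,
        }
        with_gene = make_genotype(
            FW | CEN_B01 | TEL_A, alleles={"2DL1": ("2DL1*004", "2DL1*007")}
        )
        base = classify_diplotype(with_gene)
        assert base.cen.cen_b_subtype is CenBSubtype.B01B01
        # removing 2DL1 (and its block partner 2DP1) leaves a B02-compatible
        # pattern only if the rest of the block is also absent
        without = make_genotype(FW | CEN_B02 | TEL_A)
        after = classify_diplotype(without)
        assert order[after.cen.cen_b_subtype] <= order[base.cen.cen_b_subtype]
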