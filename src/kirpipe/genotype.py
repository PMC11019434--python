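"""Donor KIR genotype parsing and haplotype-motif classification.

The KIR locus segregates as two independently classifiable halves, a
centromeric (cen) and a telomeric (tel) motif, each of which belongs to
one of two broad haplotype groups: *A* (fixed, mostly inhibitory gene
content) or *B* (carrying one or more activating genes).  An individual
therefore carries a cen diplotype and a tel diplotype (A/A, A/B or B/B),
and the centromeric B motif further splits into the *B01* subtype (with
the 2DL5-2DS3/5-2DP1-2DL1 gene block) and the *B02* subtype (without it).

Because typing reports per-gene presence/absence (optionally with
allele-level calls), classification works by matching the observed gene
content against a compatibility matrix of motif pairs defined in an
editable rule table (``data/kir_motif_rules.yaml``).  Gene-content
patterns compatible with no motif pair are reported as unclassifiable
rather than forced into a class.
"""

from __future__ import annotations

import functools
import itertools
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "KIR_LOCI",
    "FRAMEWORK_GENES",
    "GeneState",
    "GeneStatus",
    "DonorKirGenotype",
    "GenotypeClass",
    "CenBSubtype",
    "CooleyCategory",
    "RegionDiplotype",
    "KirDiplotypeClassification",
    "MotifRules",
    "load_motif_rules",
    "parse_genotype_table",
    "assign_region_genotype",
    "assign_cen_b_subtype",
    "classify_diplotype",
]

#: The 16 KIR loci, in genomic order.
KIR_LOCI = (
    "3DL3", "2DS2", "2DL2", "2DL3", "2DP1", "2DL1", "3DP1", "2DL4",
    "3DL1", "3DS1", "2DL5", "2DS3", "2DS5", "2DS1", "2DS4", "3DL2",
)

#: Framework genes present on (virtually) every haplotype.
FRAMEWORK_GENES = ("3DL3", "3DP1", "2DL4", "3DL2")

_ALLELE_RE = re.compile(r"^(?:KIR)?([23]D[LSP]\d[AB]?)\*(\d{3,})$")
_BARE_ALLELE_RE = re.compile(r"^\d{3,}$")


class GeneState(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class GenotypeClass(str, Enum):
    AA = "AA"
    AB = "AB"
    BB = "BB"
    UNCLASSIFIABLE = "unclassifiable"


class CenBSubtype(str, Enum):
    B01B01 = "B01B01"
    B01B02 = "B01B02"
    B02B02 = "B02B02"
    UNDETERMINED = "undetermined"
    NOT_APPLICABLE = "not_applicable"


class CooleyCategory(str, Enum):
    NEUTRAL = "Neutral"
    BETTER = "Better"
    BEST = "Best"
    UNCLASSIFIED = "unclassified"


def normalize_locus(name: str) -> str:
    """Map 'KIR2DL1', 'kir2dl1' or '2DL1' to the canonical locus name."""
    name = name.strip().upper()
    if name.startswith("KIR"):
        name = name[3:]
    return name


@dataclass(frozen=True)
class GeneStatus:
    """Presence/absence call for one KIR locus, optionally with alleles.

    ``copy_number`` is the number of gene copies when known (e.g. from
    allele-level typing with quantitative read support); two distinct
    called alleles imply at least two copies.
    """

    state: GeneState = GeneState.UNKNOWN
    alleles: tuple[str, ...] = ()
    copy_number: int | None = None

    def __post_init__(self) -> None:
        if self.state is GeneState.ABSENT:
            if self.alleles:
                raise ValueError("absent gene cannot carry alleles")
            if self.copy_number not in (None, 0):
                raise ValueError("absent gene must have copy_number 0")
        if self.state is GeneState.PRESENT and self.copy_number is not None:
            if self.copy_number < 1:
                raise ValueError("present gene must have copy_number >= 1")
        for allele in self.alleles:
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"allele name {allele!r} is not GENE*NNN format")

    @property
    def distinct_alleles(self) -> int:
        return len(set(self.alleles))

    @property
    def evident_copies(self) -> int | None:
        """Best lower-bound evidence for the copy number, or None."""
        if self.copy_number is not None:
            return self.copy_number
        if self.distinct_alleles >= 2:
            return self.distinct_alleles
        return None


PRESENT = GeneStatus(GeneState.PRESENT)
ABSENT = GeneStatus(GeneState.ABSENT)
UNKNOWN = GeneStatus(GeneState.UNKNOWN)


@dataclass
class DonorKirGenotype:
    """Per-locus gene status for one donor across all 16 KIR loci."""

    donor_id: str
    genes: dict[str, GeneStatus]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        fixed: dict[str, GeneStatus] = {}
        for locus, status in self.genes.items():
            fixed[normalize_locus(locus)] = status
        for locus in KIR_LOCI:
            fixed.setdefault(locus, UNKNOWN)
        extra = set(fixed) - set(KIR_LOCI)
        if extra:
            raise ValueError(f"unknown KIR loci: {sorted(extra)}")
        self.genes = {locus: fixed[locus] for locus in KIR_LOCI}
        for locus in FRAMEWORK_GENES:
            if self.genes[locus].state is GeneState.ABSENT:
                self.warnings.append(f"framework gene {locus} reported absent")

    @property
    def is_valid(self) -> bool:
        return not any(
            self.genes[locus].state is GeneState.ABSENT for locus in FRAMEWORK_GENES
        )

    def state(self, locus: str) -> GeneState:
        return self.genes[normalize_locus(locus)].state

    def status(self, locus: str) -> GeneStatus:
        return self.genes[normalize_locus(locus)]

    def state_key(self) -> tuple[str, ...]:
        """Hashable presence-pattern key (state per locus, genomic order)."""
        return tuple(self.genes[locus].state.value for locus in KIR_LOCI)


@dataclass(frozen=True)
class RegionDiplotype:
    region: str  # "cen" or "tel"
    genotype_class: GenotypeClass
    cen_b_subtype: CenBSubtype = CenBSubtype.NOT_APPLICABLE

    def __post_init__(self) -> None:
        if self.cen_b_subtype is not CenBSubtype.NOT_APPLICABLE:
            if not (self.region == "cen" and self.genotype_class is GenotypeClass.BB):
                raise ValueError("cen_b_subtype only applies to cen B/B diplotypes")


@dataclass(frozen=True)
class KirDiplotypeClassification:
    cen: RegionDiplotype
    tel: RegionDiplotype
    b_motif_count: int | None
    cooley_category: CooleyCategory
    is_double_homozygous: bool
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Rule table


@dataclass(eq=False)  # identity-hashed: used as a cache key for matching
class MotifRules:
    """Parsed motif rule table (see ``data/kir_motif_rules.yaml``)."""

    framework_genes: tuple[str, ...]
    shared_genes: tuple[str, ...]
    slots: tuple[tuple[str, tuple[str, ...]], ...]  # (slot name, member genes)
    motif_genes: Mapping[str, frozenset[str]]
    motif_type: Mapping[str, str]  # motif -> "A" | "B"
    motif_subtype: Mapping[str, str | None]
    region_motifs: Mapping[str, tuple[str, ...]]  # region -> motif names

    @functools.cached_property
    def region_unique_genes(self) -> dict[str, frozenset[str]]:
        """Genes attributable to exactly one region (and not slot/shared)."""
        slot_members = {g for _, genes in self.slots for g in genes}
        skip = set(self.shared_genes) | slot_members | set(self.framework_genes)
        out: dict[str, set[str]] = {r: set() for r in self.region_motifs}
        for region, motifs in self.region_motifs.items():
            for m in motifs:
                out[region] |= self.motif_genes[m]
        for region in out:
            others = set().union(
                *(out[r] for r in out if r != region)
            )
            out[region] = (out[region] - others) - skip
        return {r: frozenset(g) for r, g in out.items()}

    @functools.cached_property
    def diplotype_combos(self) -> tuple[tuple[tuple[str, str], ...], ...]:
        """All (cen pair, tel pair, ...) motif-pair combinations, one pair
        per region, pairs unordered."""
        per_region = []
        for region, motifs in self.region_motifs.items():
            per_region.append(
                tuple(itertools.combinations_with_replacement(motifs, 2))
            )
        return tuple(itertools.product(*per_region))

    def pair_class(self, pair: tuple[str, str]) -> GenotypeClass:
        kinds = sorted(self.motif_type[m] for m in pair)
        return GenotypeClass("".join(kinds))


def load_motif_rules(path: str | Path | None = None) -> MotifRules:
    """Load the motif rule table; defaults to the shipped configuration."""
    if path is None:
        text = (resources.files("kirpipe.data") / "kir_motif_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    motifs = raw["motifs"]
    slot_names = {s["name"] for s in raw.get("slots", [])}
    motif_genes = {
        name: frozenset(normalize_locus(g) if g not in slot_names else g
                        for g in spec["genes"])
        for name, spec in motifs.items()
    }
    region_motifs = {
        region: tuple(spec["a_motifs"]) + tuple(spec["b_motifs"])
        for region, spec in raw["regions"].items()
    }
    return MotifRules(
        framework_genes=tuple(normalize_locus(g) for g in raw["framework_genes"]),
        shared_genes=tuple(normalize_locus(g) for g in raw.get("shared_genes", [])),
        slots=tuple(
            (s["name"], tuple(normalize_locus(g) for g in s["genes"]))
            for s in raw.get("slots", [])
        ),
        motif_genes=motif_genes,
        motif_type={name: spec["type"] for name, spec in motifs.items()},
        motif_subtype={name: spec.get("subtype") for name, spec in motifs.items()},
        region_motifs=region_motifs,
    )


_DEFAULT_RULES: MotifRules | None = None


def default_motif_rules() -> MotifRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_motif_rules()
    return _DEFAULT_RULES


# ---------------------------------------------------------------------------
# Compatibility matching

_TRI = {GeneState.PRESENT: True, GeneState.ABSENT: False, GeneState.UNKNOWN: None}


@functools.lru_cache(maxsize=16384)
def _compatible_combos(
    state_key: tuple[str, ...],
    rules: MotifRules,
    enforce: frozenset[str] | None = None,
) -> tuple[tuple[tuple[str, str], ...], ...]:
    """All motif-pair combinations compatible with a presence pattern.

    Unknown gene states act as wildcards.  Matching covers region-unique
    genes (presence must equal union of the pair's motif contents),
    shared genes (present iff carried by >=1 of the four motif copies)
    and interchangeable slots (the number of distinct member genes
    present must be between 1 and the slot count when slots exist, and
    zero otherwise).  ``enforce`` restricts the region-unique checks to a
    subset of regions (shared/slot checks always apply), so one region
    can be classified without being blocked by an aberrant pattern in
    the other.
    """
    states = {locus: _TRI[GeneState(s)] for locus, s in zip(KIR_LOCI, state_key)}
    regions = list(rules.region_motifs)
    unique = rules.region_unique_genes
    matches = []
    for combo in rules.diplotype_combos:
        motifs = [m for pair in combo for m in pair]
        ok = True
        for region, pair in zip(regions, combo):
            if enforce is not None and region not in enforce:
                continue
            union = rules.motif_genes[pair[0]] | rules.motif_genes[pair[1]]
            for gene in unique[region]:
                obs = states.get(gene)
                if obs is not None and obs != (gene in union):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        for gene in rules.shared_genes:
            carriers = sum(gene in rules.motif_genes[m] for m in motifs)
            obs = states.get(gene)
            if obs is not None and obs != (carriers > 0):
                ok = False
                break
        if not ok:
            continue
        for slot_name, members in rules.slots:
            slots = sum(slot_name in rules.motif_genes[m] for m in motifs)
            obs = [states.get(g) for g in members]
            n_present = sum(1 for o in obs if o is True)
            n_known = sum(1 for o in obs if o is not None)
            if slots == 0:
                if n_present > 0:
                    ok = False
            else:
                if n_present > min(len(members), slots):
                    ok = False
                elif n_known == len(members) and n_present == 0:
                    ok = False
            if not ok:
                break
        if ok:
            matches.append(combo)
    return tuple(matches)


def _region_class(
    combos: Sequence[tuple[tuple[str, str], ...]],
    region_index: int,
    rules: MotifRules,
) -> GenotypeClass:
    classes = {rules.pair_class(combo[region_index]) for combo in combos}
    if len(classes) == 1:
        return classes.pop()
    return GenotypeClass.UNCLASSIFIABLE


def assign_region_genotype(
    g: DonorKirGenotype, region: str, rules: MotifRules | None = None
) -> RegionDiplotype:
    """Assign the A/B diplotype class of one region (``cen`` or ``tel``).

    Returns ``unclassifiable`` when the gene-content pattern matches no
    motif pair in the rule table, or when unknown gene states leave the
    class ambiguous.
    """
    rules = rules or default_motif_rules()
    if region not in rules.region_motifs:
        raise ValueError(f"unknown region {region!r}")
    combos = _compatible_combos(g.state_key(), rules, frozenset({region}))
    idx = list(rules.region_motifs).index(region)
    if not combos:
        return RegionDiplotype(region, GenotypeClass.UNCLASSIFIABLE)
    cls = _region_class(combos, idx, rules)
    if cls is GenotypeClass.UNCLASSIFIABLE:
        g.warnings.append(
            f"{region} class ambiguous (unknown state in a decisive marker gene)"
        )
    return RegionDiplotype(region, cls)


def assign_cen_b_subtype(
    g: DonorKirGenotype,
    cen: RegionDiplotype,
    rules: MotifRules | None = None,
) -> CenBSubtype:
    """Resolve the B01/B02 composition of a centromeric B/B diplotype.

    B02 lacks the 2DL5-2DS3/5-2DP1-2DL1 block of B01; with the block
    absent the diplotype is B02/B02.  Distinguishing B01/B01 from
    B01/B02 requires positive copy-number evidence at 2DL1 (two copies
    or two distinct alleles -> B01/B01; a known single copy -> B01/B02);
    a single allele call without copy information stays undetermined.
    """
    if cen.genotype_class is not GenotypeClass.BB:
        raise ValueError("cen B subtype is only defined for cen B/B diplotypes")
    rules = rules or default_motif_rules()
    combos = _compatible_combos(g.state_key(), rules, frozenset({"cen"}))
    idx = list(rules.region_motifs).index("cen")
    pairs = {
        tuple(sorted(rules.motif_subtype[m] or "?" for m in combo[idx]))
        for combo in combos
        if rules.pair_class(combo[idx]) is GenotypeClass.BB
    }
    if not pairs:
        return CenBSubtype.UNDETERMINED
    if pairs == {("B02", "B02")}:
        return CenBSubtype.B02B02
    if any("B01" not in p for p in pairs):
        # ambiguous between B02/B02 and a B01-containing pair
        return CenBSubtype.UNDETERMINED
    # B01-containing: resolve the second motif by 2DL1 copy evidence.  In a
    # cen B/B genotype no cen-A motif contributes 2DL1, so 2DL1 copies count
    # B01 copies directly.
    copies = g.status("2DL1").evident_copies
    if copies is not None and copies >= 2:
        return CenBSubtype.B01B01
    if copies == 1:
        return CenBSubtype.B01B02
    return CenBSubtype.UNDETERMINED


def classify_diplotype(
    g: DonorKirGenotype, rules: MotifRules | None = None
) -> KirDiplotypeClassification:
    """Full cen/tel diplotype classification of one donor genotype.

    Combines the per-region class assignments, counts B motifs
    (A/A -> 0, A/B -> 1, B/B -> 2 per region) and applies the
    B-motif-content categories: Neutral (0-1 B motifs), Better (>=2 B
    motifs without cen B/B), Best (cen B/B, which alone contributes 2).
    """
    rules = rules or default_motif_rules()
    cen = assign_region_genotype(g, "cen", rules)
    tel = assign_region_genotype(g, "tel", rules)
    if cen.genotype_class is GenotypeClass.BB:
        cen = RegionDiplotype(
            "cen", GenotypeClass.BB, assign_cen_b_subtype(g, cen, rules)
        )
    b_counts = {GenotypeClass.AA: 0, GenotypeClass.AB: 1, GenotypeClass.BB: 2}
    unclassified = (
        cen.genotype_class is GenotypeClass.UNCLASSIFIABLE
        or tel.genotype_class is GenotypeClass.UNCLASSIFIABLE
    )
    if unclassified:
        count: int | None = None
        category = CooleyCategory.UNCLASSIFIED
        double_hom = False
    else:
        count = b_counts[cen.genotype_class] + b_counts[tel.genotype_class]
        if cen.genotype_class is GenotypeClass.BB:
            category = CooleyCategory.BEST
        elif count >= 2:
            category = CooleyCategory.BETTER
        else:
            category = CooleyCategory.NEUTRAL
        double_hom = (
            cen.genotype_class in (GenotypeClass.AA, GenotypeClass.BB)
            and tel.genotype_class in (GenotypeClass.AA, GenotypeClass.BB)
        )
    return KirDiplotypeClassification(
        cen=cen,
        tel=tel,
        b_motif_count=count,
        cooley_category=category,
        is_double_homozygous=double_hom,
        warnings=tuple(g.warnings),
    )


# ---------------------------------------------------------------------------
# Table parsing


def _parse_cell(locus: str, raw: object) -> GeneStatus:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return UNKNOWN
    text = str(raw).strip()
    if text == "" or text.lower() in ("nan", "na", "?"):
        return UNKNOWN
    upper = text.upper()
    if upper in ("POS", "+", "1", "PRESENT"):
        return PRESENT
    if upper in ("NEG", "-", "0", "ABSENT"):
        return ABSENT
    alleles = []
    for token in text.split("+"):
        token = token.strip()
        if _BARE_ALLELE_RE.match(token):
            alleles.append(f"{locus}*{token}")
        elif _ALLELE_RE.match(token.upper()):
            alleles.append(token.upper())
        else:
            raise ValueError(f"unparseable allele token {token!r} for {locus}")
    copy_number = len(alleles) if len(alleles) > 1 else None
    return GeneStatus(GeneState.PRESENT, tuple(alleles), copy_number)


def parse_genotype_table(
    path_or_buffer, *, donor_id_column: str = "donor_id"
) -> list[DonorKirGenotype]:
    """Read a delimited genotype table into :class:`DonorKirGenotype` rows.

    The table must have a donor-id column and one column per KIR locus
    (named e.g. ``2DL1`` or ``KIR2DL1``).  Cells are ``POS``, ``NEG``,
    empty (unknown) or ``+``-separated allele lists (``001+003``).  An
    optional ``<locus>_cn`` column supplies integer copy numbers.  The
    delimiter (tab or comma) is auto-detected.  Malformed cells flag the
    gene unknown and record a warning with the row's line number.
    """
    df = pd.read_csv(path_or_buffer, sep=None, engine="python", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    colmap: dict[str, str] = {}
    cn_cols: dict[str, str] = {}
    for col in df.columns:
        if col == donor_id_column:
            continue
        base = col[:-3] if col.lower().endswith("_cn") else col
        locus = normalize_locus(base)
        if locus in KIR_LOCI:
            (cn_cols if col is not base else colmap)[locus] = col
    if donor_id_column not in df.columns:
        raise ValueError(f"missing required column {donor_id_column!r}")
    missing = [locus for locus in KIR_LOCI if locus not in colmap]
    if missing:
        raise ValueError(f"missing KIR locus columns: {missing}")

    genotypes: list[DonorKirGenotype] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        record = dict(zip(df.columns, row))
        genes: dict[str, GeneStatus] = {}
        warnings: list[str] = []
        for locus in KIR_LOCI:
            try:
                status = _parse_cell(locus, record[colmap[locus]])
            except ValueError as exc:
                warnings.append(f"line {i}: {exc}; {locus} set to unknown")
                status = UNKNOWN
            if locus in cn_cols and status.state is GeneState.PRESENT:
                raw_cn = record[cn_cols[locus]]
                if raw_cn is not None and str(raw_cn).strip() not in ("", "nan"):
                    try:
                        status = replace(status, copy_number=int(float(raw_cn)))
                    except (TypeError, ValueError):
                        warnings.append(
                            f"line {i}: bad copy number {raw_cn!r} for {locus}"
                        )
            genes[locus] = status
        genotypes.append(
            DonorKirGenotype(
                donor_id=str(record[donor_id_column]), genes=genes, warnings=warnings
            )
        )
    return genotypes
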