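"""HLA KIR-ligand epitope classification and donor-patient match counting.

HLA-C alleles split into the C1 and C2 epitope groups (ligands of the
inhibitory receptors KIR2DL2/3 and KIR2DL1 respectively, and of the
activating KIR2DS1 for C2); HLA-B alleles carry either the Bw4 epitope
(a KIR3DL1 ligand, subdivided by residue 80 into Bw4-80I and Bw4-80T) or
the non-ligand Bw6 epitope.  Assignments are looked up in shipped
two-field tables (user-replaceable TSV files); alleles missing from the
table fall back to the first-field group only when every listed allele
of that group agrees, and are otherwise reported unknown.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "HLA_LOCI",
    "EpitopeTable",
    "load_epitope_table",
    "classify_hla_c",
    "classify_hla_b",
    "HlaTyping",
    "LigandProfile",
    "ligand_profile",
    "MatchSummary",
    "hla_match_grade",
    "parse_hla_table",
]

HLA_LOCI = ("A", "B", "C", "DRB1", "DQB1")

_HLA_ALLELE_RE = re.compile(r"^(?P<locus>[A-Z0-9]+)\*(?P<f1>\d{2,}):(?P<f2>\d{2,}[A-Z]?)$")

#: Bw4 epitopes outrank Bw6 when summarizing a typing (80I > 80T).
_BW_PRIORITY = ("Bw4-80I", "Bw4-80T", "Bw6")


class EpitopeTable(dict):
    """allele -> epitope lookup with agreeing first-field fallback."""

    def lookup(self, allele: str) -> str:
        if allele in self:
            return self[allele]
        first = allele.split(":")[0]
        group = {v for k, v in self.items() if k.split(":")[0] == first}
        if len(group) == 1:
            return group.pop()
        return "unknown"


def load_epitope_table(locus: str, path: str | Path | None = None) -> EpitopeTable:
    """Load the shipped (or a user-supplied) epitope table for HLA-B or -C."""
    locus = locus.upper()
    if locus not in ("B", "C"):
        raise ValueError("epitope tables exist for HLA-B and HLA-C only")
    if path is None:
        name = f"hla_{locus.lower()}_epitopes.tsv"
        text = (resources.files("kirpipe.data") / name).read_text()
        df = pd.read_csv(pd.io.common.StringIO(text), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return EpitopeTable(zip(df["allele"], df["epitope"]))


_tables: dict[str, EpitopeTable] = {}


def _default_table(locus: str) -> EpitopeTable:
    if locus not in _tables:
        _tables[locus] = load_epitope_table(locus)
    return _tables[locus]


def _check_allele(allele: str, locus: str) -> str:
    allele = allele.strip()
    m = _HLA_ALLELE_RE.match(allele)
    if not m or m.group("locus") != locus:
        raise ValueError(f"malformed HLA-{locus} allele name {allele!r}")
    return allele


def classify_hla_c(allele: str, table: EpitopeTable | None = None) -> str:
    """Epitope group ('C1', 'C2' or 'unknown') of a two-field HLA-C allele."""
    allele = _check_allele(allele, "C")
    return (table or _default_table("C")).lookup(allele)


def classify_hla_b(allele: str, table: EpitopeTable | None = None) -> str:
    """Epitope group ('Bw4-80I', 'Bw4-80T', 'Bw6' or 'unknown') of an HLA-B allele."""
    allele = _check_allele(allele, "B")
    return (table or _default_table("B")).lookup(allele)


@dataclass(frozen=True)
class HlaTyping:
    """Two-field HLA typing of one subject (two alleles per locus)."""

    subject_id: str
    alleles: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for locus, pair in self.alleles.items():
            if len(pair) != 2:
                raise ValueError(f"locus {locus} needs exactly two alleles")
            for a in pair:
                _check_allele(a, locus)

    def pair(self, locus: str) -> tuple[str, str]:
        return self.alleles[locus]


@dataclass(frozen=True)
class LigandProfile:
    """KIR-ligand summary of one HLA typing.

    ``c_group`` is the unordered pair of HLA-C epitopes; ``bw`` the
    highest-priority Bw4 epitope carried by any HLA-B allele (80I > 80T),
    or 'Bw6-only'.  ``partial`` flags profiles in which an unknown
    epitope on a decisive allele prevented a definite call.
    """

    subject_id: str
    c_group: str  # C1C1 | C1C2 | C2C2 | unknown
    bw: str  # Bw4-80I | Bw4-80T | Bw6-only | unknown
    per_allele_epitopes: tuple[tuple[str, str], ...]
    unknown_alleles: tuple[str, ...] = ()
    partial: bool = False

    @property
    def c1_positive(self) -> bool:
        return self.c_group in ("C1C1", "C1C2")

    @property
    def c2_positive(self) -> bool:
        return self.c_group in ("C1C2", "C2C2")

    @property
    def bw4_positive(self) -> bool:
        return self.bw in ("Bw4-80I", "Bw4-80T")


def ligand_profile(
    t: HlaTyping,
    c_table: EpitopeTable | None = None,
    b_table: EpitopeTable | None = None,
) -> LigandProfile:
    """Build the C1/C2 and Bw4/Bw6 ligand profile of one typing."""
    c_eps = [classify_hla_c(a, c_table) for a in t.pair("C")]
    b_eps = [classify_hla_b(a, b_table) for a in t.pair("B")]
    per_allele = tuple(zip(t.pair("C") + t.pair("B"), tuple(c_eps + b_eps)))
    unknown = tuple(a for a, e in per_allele if e == "unknown")

    if "unknown" in c_eps:
        # one known C1 with one unknown still leaves C1C1 vs C1C2 open
        c_group = "unknown"
    else:
        c_group = "".join(sorted(c_eps))

    known_b = [e for e in b_eps if e != "unknown"]
    bw4 = [e for e in known_b if e.startswith("Bw4")]
    if bw4:
        bw = min(bw4, key=_BW_PRIORITY.index)
        # an unknown allele could still carry a higher-priority Bw4 epitope
        partial_b = "unknown" in b_eps and bw != "Bw4-80I"
    elif "unknown" in b_eps:
        bw, partial_b = "unknown", True
    else:
        bw, partial_b = "Bw6-only", False
    return LigandProfile(
        subject_id=t.subject_id,
        c_group=c_group,
        bw=bw,
        per_allele_epitopes=per_allele,
        unknown_alleles=unknown,
        partial=(c_group == "unknown") or partial_b or bw == "unknown",
    )


@dataclass(frozen=True)
class MatchSummary:
    """Donor-patient HLA match count over A/B/C/DRB1/DQB1 (out of 10)."""

    matched: int
    out_of: int
    grade: str  # "10/10", "9/10", "<=8/10"
    mismatched_loci: tuple[str, ...]
    c1c2_change: bool
    bw4bw6_change: bool
    incomplete: bool = False


def _locus_matches(donor: tuple[str, str], patient: tuple[str, str]) -> int:
    """Matched allele count within one locus, best unordered pairing."""
    d1, d2 = donor
    p1, p2 = patient
    direct = (d1 == p1) + (d2 == p2)
    crossed = (d1 == p2) + (d2 == p1)
    return max(direct, crossed)


def hla_match_grade(
    donor: HlaTyping,
    patient: HlaTyping,
    c_table: EpitopeTable | None = None,
    b_table: EpitopeTable | None = None,
) -> MatchSummary:
    """Count matched alleles (out of 10) and flag KIR-ligand changes.

    A mismatched HLA-C locus where the unshared donor and patient
    alleles fall into different C1/C2 groups raises the C1-C2 change
    flag; a mismatched HLA-B locus with discordant Bw4/Bw6 status raises
    the Bw4-Bw6 flag.
    """
    matched = 0
    out_of = 0
    mismatched: list[str] = []
    incomplete = False
    for locus in HLA_LOCI:
        if locus not in donor.alleles or locus not in patient.alleles:
            incomplete = True
            continue
        out_of += 2
        n = _locus_matches(donor.pair(locus), patient.pair(locus))
        matched += n
        if n < 2:
            mismatched.append(locus)

    def _epitope_set(t: HlaTyping, locus: str) -> set[str]:
        fn = classify_hla_c if locus == "C" else classify_hla_b
        table = c_table if locus == "C" else b_table
        eps = {fn(a, table) for a in t.pair(locus)}
        if locus == "B":
            eps = {"Bw4" if e.startswith("Bw4") else e for e in eps}
        return eps

    c1c2_change = False
    if "C" in mismatched:
        c1c2_change = _epitope_set(donor, "C") != _epitope_set(patient, "C")
    bw_change = False
    if "B" in mismatched:
        bw_change = _epitope_set(donor, "B") != _epitope_set(patient, "B")

    if incomplete:
        grade = f"{matched}/{out_of}"
    elif matched == 10:
        grade = "10/10"
    elif matched == 9:
        grade = "9/10"
    else:
        grade = "<=8/10"
    return MatchSummary(
        matched=matched,
        out_of=out_of,
        grade=grade,
        mismatched_loci=tuple(mismatched),
        c1c2_change=c1c2_change,
        bw4bw6_change=bw_change,
        incomplete=incomplete,
    )


def parse_hla_table(path_or_buffer) -> list[HlaTyping]:
    """Read a typing table (subject_id, A_1, A_2, ..., DQB1_2) into typings."""
    df = pd.read_csv(path_or_buffer, sep=None, engine="python", dtype=str)
    typings = []
    for _, row in df.iterrows():
        alleles = {}
        for locus in HLA_LOCI:
            c1, c2 = f"{locus}_1", f"{locus}_2"
            if c1 in df.columns and c2 in df.columns:
                if pd.notna(row[c1]) and pd.notna(row[c2]):
                    alleles[locus] = (row[c1].strip(), row[c2].strip())
        typings.append(HlaTyping(subject_id=str(row["subject_id"]), alleles=alleles))
    return typings
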