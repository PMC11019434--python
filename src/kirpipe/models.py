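"""Donor-KIR / patient-ligand interaction classifiers and scores.

Implements the classifier families used in donor KIR genotype association
studies: phylogenetic clade presence for KIR2DL1/KIR2DL3, the
KIR2DS1-by-HLA-C and KIR3DL1-by-HLA-B groupings, the functional
inhibitory-KIR count, weighted KIR-ligand score families (missing /
inhibitory / activating / weighted / inhibitory-missing), and named
genotype signature flags.

All model parameters (clade membership, KIR3DL1 expression subtypes,
score weights, signature gene sets) come from an editable YAML config;
the shipped defaults are reconstructed placeholders and the config
checksum is recorded in analysis reports so runs are attributable to a
specific parameterization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .genotype import DonorKirGenotype, GeneState, KIR_LOCI, normalize_locus
from .ligands import LigandProfile

__all__ = [
    "ScoreConfig",
    "load_score_config",
    "clade_presence",
    "kir2ds1_class",
    "kir3dl1_subtype",
    "kir3dl1_inhibition_class",
    "functional_ikir_count",
    "weighted_kir_scores",
    "signature_flags",
    "interaction_profile",
]

_STATES = ("ligand_present", "ligand_missing", "receptor_missing")
_LIGANDS = ("C1", "C2", "Bw4", "Bw4-80I", "Bw4-80T")


@dataclass(eq=False)
class ScoreConfig:
    """Parsed model configuration (see ``data/kir_model_config.yaml``)."""

    clades: Mapping[str, Mapping[str, tuple[str, ...]]]
    kir3dl1_subtypes: Mapping[str, tuple[str, ...]]
    kir3dl1_inhibition: Mapping[str, object]
    functional_ikir: tuple[dict, ...]
    scores: Mapping[str, tuple[dict, ...]]
    signatures: Mapping[str, dict]
    checksum: str

    def clade_of(self, gene: str, allele: str) -> str | None:
        for clade, alleles in self.clades.get(gene, {}).items():
            if allele in alleles:
                return clade
        return None

    def subtype_of(self, allele: str) -> str | None:
        for subtype, alleles in self.kir3dl1_subtypes.items():
            if allele in alleles:
                return subtype
        return None


def _validate_terms(terms: Sequence[dict], where: str) -> tuple[dict, ...]:
    out = []
    for term in terms:
        gene = normalize_locus(str(term["gene"]))
        if gene not in KIR_LOCI:
            raise ValueError(f"{where}: unknown KIR gene {term['gene']!r}")
        ligand = term.get("ligand")
        if ligand is not None and ligand not in _LIGANDS:
            raise ValueError(f"{where}: unknown ligand group {ligand!r}")
        state = term.get("state", "ligand_present")
        if state not in _STATES:
            raise ValueError(f"{where}: unknown interaction state {state!r}")
        weight = float(term.get("weight", 1.0))
        if not weight == weight or weight in (float("inf"), float("-inf")):
            raise ValueError(f"{where}: non-finite weight")
        out.append({"gene": gene, "ligand": ligand, "state": state, "weight": weight})
    return tuple(out)


def load_score_config(path: str | Path | None = None) -> ScoreConfig:
    """Load and validate a model config; defaults to the shipped file."""
    if path is None:
        text = (resources.files("kirpipe.data") / "kir_model_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    clades = {
        normalize_locus(gene): {
            clade: tuple(alleles) for clade, alleles in by_clade.items()
        }
        for gene, by_clade in raw.get("clades", {}).items()
    }
    for gene, by_clade in clades.items():
        seen: dict[str, str] = {}
        for clade, alleles in by_clade.items():
            for a in alleles:
                if a in seen:
                    raise ValueError(
                        f"allele {a} assigned to clades {seen[a]} and {clade}"
                    )
                seen[a] = clade
    signatures = {}
    for name, spec in raw.get("signatures", {}).items():
        for key in ("present", "absent"):
            for gene in spec.get(key, []):
                if normalize_locus(gene) not in KIR_LOCI:
                    raise ValueError(f"signature {name}: unknown gene {gene!r}")
        signatures[name] = {
            "present": tuple(normalize_locus(g) for g in spec.get("present", [])),
            "absent": tuple(normalize_locus(g) for g in spec.get("absent", [])),
            "subset": spec.get("subset"),
        }
    return ScoreConfig(
        clades=clades,
        kir3dl1_subtypes={
            k: tuple(v) for k, v in raw.get("kir3dl1_subtypes", {}).items()
        },
        kir3dl1_inhibition=raw.get("kir3dl1_inhibition", {}),
        functional_ikir=_validate_terms(
            raw.get("functional_ikir", []), "functional_ikir"
        ),
        scores={
            name: _validate_terms(terms, f"scores.{name}")
            for name, terms in raw.get("scores", {}).items()
        },
        signatures=signatures,
        checksum=hashlib.sha256(text.encode()).hexdigest()[:16],
    )


_default_cfg: ScoreConfig | None = None


def default_score_config() -> ScoreConfig:
    global _default_cfg
    if _default_cfg is None:
        _default_cfg = load_score_config()
    return _default_cfg


# ---------------------------------------------------------------------------
# Classifiers


def clade_presence(
    g: DonorKirGenotype, gene: str, clade: str, cfg: ScoreConfig | None = None
) -> str:
    """'present' / 'absent' / 'unknown' for a phylogenetic clade at one gene.

    Present iff any called allele maps to the clade; an absent gene is
    'absent' (not an error); a present gene whose alleles include an
    unmapped name, none of which maps to the clade, is 'unknown'.
    """
    cfg = cfg or default_score_config()
    gene = normalize_locus(gene)
    if gene not in cfg.clades:
        raise ValueError(f"no clade table for gene {gene}")
    status = g.status(gene)
    if status.state is GeneState.ABSENT:
        return "absent"
    if status.state is GeneState.UNKNOWN or not status.alleles:
        return "unknown"
    mapped = [cfg.clade_of(gene, a) for a in status.alleles]
    if clade in mapped:
        return "present"
    if None in mapped:
        return "unknown"
    return "absent"


def kir2ds1_class(g: DonorKirGenotype, p: LigandProfile) -> str:
    """KIR2DS1/HLA-C grouping: 'neg', 'pos_C1plus', 'pos_C2C2' or 'unknown'."""
    state = g.state("2DS1")
    if state is GeneState.ABSENT:
        return "neg"
    if state is GeneState.UNKNOWN or p.c_group == "unknown":
        return "unknown"
    return "pos_C2C2" if p.c_group == "C2C2" else "pos_C1plus"


def kir3dl1_subtype(g: DonorKirGenotype, cfg: ScoreConfig | None = None) -> str:
    """Expression subtype of the donor's KIR3DL1: high/low/null/absent/unknown.

    With two called alleles the higher-expression allotype dominates
    (high > low > null), reflecting that inhibition requires at least one
    expressed receptor copy.
    """
    cfg = cfg or default_score_config()
    status = g.status("3DL1")
    if status.state is GeneState.ABSENT:
        return "absent"
    if status.state is GeneState.UNKNOWN or not status.alleles:
        return "unknown"
    mapped = [cfg.subtype_of(a) for a in status.alleles]
    rank = {"high": 0, "low": 1, "null": 2}
    known = [m for m in mapped if m is not None]
    if None in mapped and (not known or min(rank[m] for m in known) > 0):
        return "unknown"
    return min(known, key=lambda m: rank[m])


def kir3dl1_inhibition_class(
    g: DonorKirGenotype, p: LigandProfile, cfg: ScoreConfig | None = None
) -> str:
    """KIR3DL1-mediated inhibition strength: 'strong', 'weak', 'non', 'unknown'.

    Looked up in the configured subtype-by-Bw decision table; any pairing
    with a Bw6-only patient, a null allotype or an absent receptor is
    non-inhibiting.
    """
    cfg = cfg or default_score_config()
    subtype = kir3dl1_subtype(g, cfg)
    if subtype == "absent":
        return str(cfg.kir3dl1_inhibition.get("absent", "non"))
    if subtype == "unknown" or p.bw == "unknown":
        return "unknown"
    row = cfg.kir3dl1_inhibition.get(subtype)
    if row is None:
        return "unknown"
    if isinstance(row, str):
        return row
    return str(row[p.bw])


def _ligand_present(p: LigandProfile, ligand: str) -> bool:
    if ligand == "C1":
        return p.c1_positive
    if ligand == "C2":
        return p.c2_positive
    if ligand == "Bw4":
        return p.bw4_positive
    if ligand in ("Bw4-80I", "Bw4-80T"):
        return p.bw == ligand
    raise ValueError(f"unknown ligand group {ligand!r}")


def functional_ikir_count(
    g: DonorKirGenotype, p: LigandProfile, cfg: ScoreConfig | None = None
) -> int | None:
    """Number of inhibitory KIR whose cognate patient ligand is present.

    Counts the canonical pairs 2DL1-C2, 2DL2-C1, 2DL3-C1 and 3DL1-Bw4
    (configurable).  Returns None with a partial ligand profile or an
    unknown state at a counted gene.
    """
    cfg = cfg or default_score_config()
    if p.partial:
        return None
    count = 0
    for pair in cfg.functional_ikir:
        state = g.state(pair["gene"])
        if state is GeneState.UNKNOWN:
            return None
        if state is GeneState.PRESENT and _ligand_present(p, pair["ligand"]):
            count += 1
    return count


def weighted_kir_scores(
    g: DonorKirGenotype, p: LigandProfile, cfg: ScoreConfig | None = None
) -> dict[str, float | None]:
    """Evaluate every configured weighted KIR-ligand score for one pair.

    Each score is a sum of weight x indicator terms over
    (receptor, ligand, interaction-state) triples; scores touching an
    unknown gene state or a partial ligand profile are None.
    """
    cfg = cfg or default_score_config()
    out: dict[str, float | None] = {}
    for name, terms in cfg.scores.items():
        total = 0.0
        ok = not p.partial
        for term in terms:
            if not ok:
                break
            state = g.state(term["gene"])
            if state is GeneState.UNKNOWN:
                ok = False
                break
            gene_present = state is GeneState.PRESENT
            lig = _ligand_present(p, term["ligand"])
            hit = {
                "ligand_present": gene_present and lig,
                "ligand_missing": gene_present and not lig,
                "receptor_missing": (not gene_present) and lig,
            }[term["state"]]
            if hit:
                total += term["weight"]
        out[name] = total if ok else None
    return out


def signature_flags(
    g: DonorKirGenotype, cfg: ScoreConfig | None = None
) -> dict[str, bool | None]:
    """Evaluate named genotype signatures (conjunctions of gene conditions).

    A flag is True iff every 'present' gene is present and every 'absent'
    gene is absent; None when an involved gene state is unknown.  The
    per-signature patient-subset context is applied downstream by the
    analysis pipeline, not here.
    """
    cfg = cfg or default_score_config()
    out: dict[str, bool | None] = {}
    for name, spec in cfg.signatures.items():
        value: bool | None = True
        for gene in spec["present"]:
            state = g.state(gene)
            if state is GeneState.UNKNOWN:
                value = None
                break
            if state is GeneState.ABSENT:
                value = False
                break
        if value:
            for gene in spec["absent"]:
                state = g.state(gene)
                if state is GeneState.UNKNOWN:
                    value = None
                    break
                if state is GeneState.PRESENT:
                    value = False
                    break
        out[name] = value
    return out


def interaction_profile(
    g: DonorKirGenotype, p: LigandProfile, cfg: ScoreConfig | None = None
) -> dict[str, object]:
    """All classifier levels and scores for one donor-patient pair."""
    cfg = cfg or default_score_config()
    row: dict[str, object] = {
        "donor_id": g.donor_id,
        "patient_id": p.subject_id,
        "kir2ds1_class": kir2ds1_class(g, p),
        "kir3dl1_class": kir3dl1_inhibition_class(g, p, cfg),
        "functional_ikir_count": functional_ikir_count(g, p, cfg),
    }
    for gene, by_clade in cfg.clades.items():
        for clade in by_clade:
            row[f"{gene}_{clade}"] = clade_presence(g, gene, clade, cfg)
    row.update(weighted_kir_scores(g, p, cfg))
    for name, flag in signature_flags(g, cfg).items():
        row[f"signature_{name}"] = flag
    return row
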