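"""Synthetic transplant-cohort generator with planted outcome effects.

Generates donor-recipient cohorts with the statistical structure the
analysis pipeline assumes, so every stage can be exercised without
registry data:

* donor KIR diplotypes drawn from a configurable 3x3 cen x tel frequency
  table (plus an unclassifiable fraction), with gene content realized
  from motif templates so the genotype classifier recovers the drawn
  labels exactly;
* patient C1/C2 and Bw4/Bw6 ligand groups and adjustment covariates drawn
  independently (donor KIR and patient HLA are independent in
  unrelated-donor pairs);
* competing-risks outcomes from constant cause-specific hazards
  (relapse/progression and non-relapse death), calibrated in closed form
  to 2-year anchor probabilities, with multiplicative planted hazard
  ratios for configurable donor groups and administrative (plus optional
  random exponential) censoring.

Randomness uses ``numpy.random.default_rng`` (PCG64); a scenario's seed
fully determines the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype import (
    DonorKirGenotype,
    GeneState,
    GeneStatus,
    KIR_LOCI,
    MotifRules,
    classify_diplotype,
    default_motif_rules,
)

__all__ = [
    "ScenarioConfig",
    "load_scenario",
    "default_calibration",
    "SyntheticCohort",
    "generate_cohort",
    "plant_effect_roundtrip",
]

_CEN_CLASSES = ("AA", "AB", "BB")
_TEL_CLASSES = ("AA", "AB", "BB")


def default_calibration(
    efs: float = 0.51,
    cif_relapse: float = 0.29,
    cif_nrm: float = 0.20,
    at_years: float = 2.0,
) -> tuple[float, float]:
    """Constant cause-specific hazards matching 2-year anchor probabilities.

    With constant hazards and administrative censoring only, event-free
    survival is ``exp(-(l1+l2) t)`` and the cumulative incidence of cause
    k is ``l_k/(l1+l2) (1 - exp(-(l1+l2) t))``, so the anchors invert in
    closed form::

        l_total   = -ln(EFS(t*)) / t*
        l_relapse = l_total * CIF_rel(t*) / (CIF_rel(t*) + CIF_nrm(t*))
        l_nrm     = l_total - l_relapse

    Returns (relapse hazard, NRM hazard) per year.  The anchors must
    partition unity: EFS + CIF_rel + CIF_nrm = 1 at the anchor time.
    """
    if not (0.0 < efs <= 1.0 and 0.0 <= cif_relapse < 1.0 and 0.0 <= cif_nrm < 1.0):
        raise ValueError("anchor probabilities out of range")
    if abs(efs + cif_relapse + cif_nrm - 1.0) > 1e-9:
        raise ValueError(
            "inconsistent anchors: EFS + CIF_relapse + CIF_NRM must equal 1"
        )
    if efs == 1.0:
        return 0.0, 0.0
    lam_total = -math.log(efs) / at_years
    lam_relapse = lam_total * cif_relapse / (cif_relapse + cif_nrm)
    return lam_relapse, lam_total - lam_relapse


@dataclass
class ScenarioConfig:
    """Validated scenario parameters (see ``data/scenarios/*.yaml``)."""

    name: str
    n: int
    horizon_years: float
    anchors: dict
    diplotype_counts: dict
    unclassifiable_count: float
    cen_b01_fraction: float
    ligand_freqs: dict
    bw_freqs: dict
    covariates: dict
    planted_effects: list
    censoring_rate_per_year: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if not 0.0 <= self.cen_b01_fraction <= 1.0:
            raise ValueError("cen_b01_fraction must be a probability")
        for freqs, what in ((self.ligand_freqs, "ligand"), (self.bw_freqs, "Bw")):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{what} frequencies sum to {total}, not 1")
        for eff in self.planted_effects:
            for key in ("hr_relapse", "hr_nrm"):
                if eff.get(key, 1.0) <= 0:
                    raise ValueError("planted hazard ratios must be positive")
        self.hazards = default_calibration(
            self.anchors["efs"],
            self.anchors["cif_relapse"],
            self.anchors["cif_nrm"],
            self.anchors.get("at_years", 2.0),
        )

    @property
    def cell_probabilities(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        cells = [(c, t) for c in _CEN_CLASSES for t in _TEL_CLASSES]
        counts = np.array(
            [self.diplotype_counts[c][t] for c, t in cells]
            + [self.unclassifiable_count],
            dtype=float,
        )
        return cells + [("unclassifiable", "unclassifiable")], counts / counts.sum()


def load_scenario(name_or_path: str | Path, **overrides) -> ScenarioConfig:
    """Load a shipped scenario by name or a scenario YAML by path.

    A scenario may name a ``base`` scenario whose keys it overrides.
    Keyword overrides (e.g. ``n=...``) take final precedence.
    """
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        res = resources.files("kirpipe.data") / "scenarios" / f"{name_or_path}.yaml"
        try:
            raw = yaml.safe_load(res.read_text())
        except FileNotFoundError:
            raise FileNotFoundError(f"no shipped scenario named {name_or_path!r}")
    if "base" in raw:
        base = load_scenario(raw.pop("base"))
        merged = {**base.__dict__}
        merged.pop("hazards", None)
        merged.update(raw)
        raw = merged
    raw.update(overrides)
    raw = {k: v for k, v in raw.items() if k in ScenarioConfig.__dataclass_fields__}
    return ScenarioConfig(**raw)


# ---------------------------------------------------------------------------
# Genotype templates

# Gene content per motif, mirroring the shipped motif rule table.  The
# template consistency with the rule table is asserted at generation time
# by round-tripping one exemplar of every diplotype through the
# classifier.
_MOTIF_GENES = {
    "cenA": {"2DL3", "2DP1", "2DL1"},
    "cenB01": {"2DS2", "2DL2", "2DL5", "2DP1", "2DL1"},
    "cenB02": {"2DS2", "2DL2"},
    "telA": {"3DL1", "2DS4"},
    "telB": {"3DS1", "2DL5", "2DS1"},
}
_FRAMEWORK = {"3DL3", "3DP1", "2DL4", "3DL2"}

#: allele pools sampled for allele-bearing genes (drawn uniformly)
_ALLELE_POOLS = {
    "2DL1": ("2DL1*001", "2DL1*002", "2DL1*003", "2DL1*004", "2DL1*007", "2DL1*008"),
    "2DL3": ("2DL3*001", "2DL3*002", "2DL3*005", "2DL3*009"),
    "3DL1": ("3DL1*001", "3DL1*002", "3DL1*004", "3DL1*005", "3DL1*007", "3DL1*015"),
}


def _realize_genes(
    cen_pair: tuple[str, ...], tel_pair: tuple[str, ...], rng: np.random.Generator
) -> tuple[set[str], dict[str, int]]:
    """Present-gene set and copy counts for a motif-pair combination."""
    present = set(_FRAMEWORK)
    copies: dict[str, int] = {}
    motifs = [f"cen{m}" for m in cen_pair] + [f"tel{m}" for m in tel_pair]
    slot_count = 0
    for m in motifs:
        genes = _MOTIF_GENES[m]
        present |= genes
        for gene in ("2DL1", "2DL3", "3DL1"):
            if gene in genes:
                copies[gene] = copies.get(gene, 0) + 1
        if m in ("cenB01", "telB"):
            slot_count += 1
            # the 2DS3/2DS5 slot: cen B01 usually carries 2DS3, tel B 2DS5
            p_2ds3 = 0.8 if m == "cenB01" else 0.2
            present.add("2DS3" if rng.random() < p_2ds3 else "2DS5")
    return present, copies


def _exemplar_genotype(
    cen_pair: tuple[str, ...], tel_pair: tuple[str, ...], rng: np.random.Generator
) -> DonorKirGenotype:
    present, copies = _realize_genes(cen_pair, tel_pair, rng)
    genes: dict[str, GeneStatus] = {}
    for locus in KIR_LOCI:
        if locus not in present:
            genes[locus] = GeneStatus(GeneState.ABSENT)
        elif locus in copies:
            pool = _ALLELE_POOLS[locus]
            k = copies[locus]
            alleles = tuple(sorted(rng.choice(pool, size=min(k, len(pool)), replace=False)))
            genes[locus] = GeneStatus(GeneState.PRESENT, alleles, k)
        else:
            genes[locus] = GeneStatus(GeneState.PRESENT)
    return DonorKirGenotype("exemplar", genes)


def _validate_templates(rules: MotifRules, rng: np.random.Generator) -> None:
    """Hard error if any template classifies differently than drawn."""
    for cen_pair in (("A", "A"), ("A", "B01"), ("A", "B02"),
                     ("B01", "B01"), ("B01", "B02"), ("B02", "B02")):
        for tel_pair in (("A", "A"), ("A", "B"), ("B", "B")):
            g = _exemplar_genotype(cen_pair, tel_pair, rng)
            cls = classify_diplotype(g, rules)
            want_cen = "".join(sorted("A" if m == "A" else "B" for m in cen_pair))
            want_tel = "".join(sorted(tel_pair))
            got_cen = cls.cen.genotype_class.value
            got_tel = cls.tel.genotype_class.value
            if (got_cen, got_tel) != (want_cen, want_tel):
                raise ValueError(
                    f"template {cen_pair}/{tel_pair} classifies as "
                    f"{got_cen}/{got_tel}: rule table and templates disagree"
                )
            if want_cen == "BB":
                want_sub = "".join(sorted(cen_pair))
                got_sub = cls.cen.cen_b_subtype.value
                if got_sub != want_sub:
                    raise ValueError(
                        f"template {cen_pair} subtype classifies as {got_sub}"
                    )


@dataclass
class SyntheticCohort:
    """A generated cohort: outcome records plus the donor genotype table."""

    config: ScenarioConfig
    seed: int
    records: pd.DataFrame
    genotype_table: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.records)


def _draw_covariates(
    spec: Mapping[str, dict], n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, cfg in spec.items():
        kind = cfg["type"]
        if kind == "normal":
            x = rng.normal(cfg["mean"], cfg["sd"], n)
            if "min" in cfg or "max" in cfg:
                x = np.clip(x, cfg.get("min", -np.inf), cfg.get("max", np.inf))
            out[name] = x
        elif kind == "bernoulli":
            out[name] = (rng.random(n) < cfg["p"]).astype(int)
        elif kind == "categorical":
            levels = list(cfg["levels"])
            probs = np.array([cfg["levels"][lv] for lv in levels], dtype=float)
            out[name] = np.array(levels, dtype=object)[
                rng.choice(len(levels), size=n, p=probs / probs.sum())
            ]
        else:
            raise ValueError(f"unknown covariate type {kind!r} for {name}")
    return out


def _effect_mask(records: pd.DataFrame, group: Mapping[str, str]) -> np.ndarray:
    colmap = {"cen": "true_cen", "tel": "true_tel", "cen_subtype": "true_cen_subtype"}
    mask = np.ones(len(records), dtype=bool)
    for key, value in group.items():
        if key not in colmap:
            raise ValueError(f"unknown planted-effect group key {key!r}")
        mask &= (records[colmap[key]] == value).to_numpy()
    return mask


def generate_cohort(
    cfg: ScenarioConfig | str, seed: int, n: int | None = None
) -> SyntheticCohort:
    """Generate one synthetic cohort; the (config, seed) pair is reproducible.

    Genotype gene content is realized from the motif templates (validated
    against the shipped rule table at each call), ligand groups and
    covariates are drawn independently, and event times come from the two
    cause-specific exponential hazards with planted multiplicative
    effects, censored administratively at the horizon.
    """
    if isinstance(cfg, str):
        cfg = load_scenario(cfg)
    if n is not None and n != cfg.n:
        cfg = _with_n(cfg, n)
    rng = np.random.default_rng(seed)
    rules = default_motif_rules()
    _validate_templates(rules, np.random.default_rng(0))

    n = cfg.n
    cells, probs = cfg.cell_probabilities
    cell_idx = rng.choice(len(cells), size=n, p=probs)

    # motif composition per record
    cen_pairs: list[tuple[str, ...]] = []
    tel_pairs: list[tuple[str, ...]] = []
    true_cen: list[str] = []
    true_tel: list[str] = []
    true_sub: list[str] = []
    p01 = cfg.cen_b01_fraction
    for i in range(n):
        cen_cls, tel_cls = cells[cell_idx[i]]
        if cen_cls == "unclassifiable":
            cen_pairs.append(("unclassifiable",))
            tel_pairs.append(("A", "A"))
            true_cen.append("unclassifiable")
            true_tel.append("unclassifiable")
            true_sub.append("not_applicable")
            continue
        n_b = {"AA": 0, "AB": 1, "BB": 2}[cen_cls]
        b_subs = tuple(
            "B01" if rng.random() < p01 else "B02" for _ in range(n_b)
        )
        cen_pair = tuple(["A"] * (2 - n_b)) + tuple(sorted(b_subs))
        tel_pair = {"AA": ("A", "A"), "AB": ("A", "B"), "BB": ("B", "B")}[tel_cls]
        cen_pairs.append(cen_pair)
        tel_pairs.append(tel_pair)
        true_cen.append(cen_cls)
        true_tel.append(tel_cls)
        true_sub.append("".join(sorted(b_subs)) if cen_cls == "BB" else "not_applicable")

    # genotype table rows (the TSV schema the parser reads)
    allele_cache: dict = {}
    rows: list[dict] = []
    for i in range(n):
        row: dict[str, object] = {"donor_id": f"D{i:06d}"}
        if cen_pairs[i][0] == "unclassifiable":
            present: set[str] = set(_FRAMEWORK) | _MOTIF_GENES["telA"]
            copies = {"3DL1": 2}
        else:
            present, copies = _realize_genes(cen_pairs[i], tel_pairs[i], rng)
        for locus in KIR_LOCI:
            if locus not in present:
                row[locus] = "NEG"
            elif locus in copies:
                pool = _ALLELE_POOLS[locus]
                k = copies[locus]
                chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
                row[locus] = "+".join(
                    sorted(pool[j].split("*")[1] for j in chosen)
                )
                row[f"{locus}_cn"] = k
            else:
                row[locus] = "POS"
        rows.append(row)
    genotype_table = pd.DataFrame(rows)
    for locus in ("2DL1", "2DL3", "3DL1"):
        col = f"{locus}_cn"
        if col in genotype_table.columns:
            genotype_table[col] = genotype_table[col].astype("Int64")

    # ligands, covariates
    lig_levels = list(cfg.ligand_freqs)
    lig_p = np.array([cfg.ligand_freqs[lv] for lv in lig_levels])
    c_group = np.array(lig_levels, dtype=object)[
        rng.choice(len(lig_levels), size=n, p=lig_p / lig_p.sum())
    ]
    bw_levels = list(cfg.bw_freqs)
    bw_p = np.array([cfg.bw_freqs[lv] for lv in bw_levels])
    bw = np.array(bw_levels, dtype=object)[
        rng.choice(len(bw_levels), size=n, p=bw_p / bw_p.sum())
    ]
    covs = _draw_covariates(cfg.covariates, n, rng)

    records = pd.DataFrame(
        {
            "donor_id": genotype_table["donor_id"],
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "true_cen": true_cen,
            "true_tel": true_tel,
            "true_cen_subtype": true_sub,
            "c_group": c_group,
            "bw": bw,
            **covs,
        }
    )

    # outcomes: competing exponential hazards with planted effects
    lam_rel, lam_nrm = cfg.hazards
    hr_rel = np.ones(n)
    hr_nrm = np.ones(n)
    for eff in cfg.planted_effects:
        mask = _effect_mask(records, eff["group"])
        if not mask.any():
            raise ValueError(
                f"planted-effect group {eff['group']} absent from generated cohort"
            )
        hr_rel[mask] *= eff.get("hr_relapse", 1.0)
        hr_nrm[mask] *= eff.get("hr_nrm", 1.0)

    def _exp_times(rate: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            scale = np.where(rate > 0, 1.0 / np.maximum(rate, 1e-300), np.inf)
        return np.where(rate > 0, rng.exponential(1.0, n) * scale, np.inf)

    t_rel = _exp_times(lam_rel * hr_rel)
    t_nrm = _exp_times(lam_nrm * hr_nrm)
    t_cens = np.full(n, cfg.horizon_years)
    if cfg.censoring_rate_per_year > 0:
        t_cens = np.minimum(
            t_cens, rng.exponential(1.0 / cfg.censoring_rate_per_year, n)
        )
    t = np.minimum.reduce([t_rel, t_nrm, t_cens])
    cause = np.where(t == t_rel, 1, np.where(t == t_nrm, 2, 0))
    records["time_months"] = np.maximum(t * 12.0, 1e-9)
    records["cause"] = cause
    return SyntheticCohort(
        config=cfg, seed=seed, records=records, genotype_table=genotype_table
    )


def _with_n(cfg: ScenarioConfig, n: int) -> ScenarioConfig:
    data = {k: v for k, v in cfg.__dict__.items() if k != "hazards"}
    data["n"] = n
    return ScenarioConfig(**data)


def plant_effect_roundtrip(
    scenario: str | ScenarioConfig,
    endpoint: str = "nrm",
    n: int | None = None,
    replicates: int = 20,
    seed: int = 0,
    adjustment: Sequence[str] = ("patient_age", "donor_age", "female_to_male"),
) -> pd.DataFrame:
    """Planted-vs-recovered hazard-ratio report for a one-effect scenario.

    For each replicate: generate a cohort, classify genotypes through the
    real classifier, fit the adjusted cause-specific Cox model for the
    endpoint and record the recovered HR with its Wald CI and whether the
    CI covers the planted value.
    """
    from .pipeline import classify_cohort  # deferred: avoids import cycle
    from .survival import coxph_cause_specific

    cfg = load_scenario(scenario) if isinstance(scenario, str) else scenario
    if len(cfg.planted_effects) != 1:
        raise ValueError("round-trip harness expects exactly one planted effect")
    eff = cfg.planted_effects[0]
    planted = eff.get("hr_nrm" if endpoint == "nrm" else "hr_relapse", 1.0)
    cause = 2 if endpoint == "nrm" else 1
    if n is not None:
        cfg = _with_n(cfg, n)

    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cohort = generate_cohort(cfg, seed=rep_seed)
        labels = classify_cohort(cohort.genotype_table)
        df = cohort.records.merge(labels, on="donor_id")
        df["flagged"] = _pipeline_group_indicator(df, eff["group"]).astype(int)
        fit = coxph_cause_specific(
            df, ["flagged", *adjustment], cause=cause, strata=["registry"]
        )
        row = fit.row("flagged[1]") if "flagged[1]" in set(fit.summary["covariate"]) \
            else fit.row("flagged")
        rows.append(
            {
                "replicate": rep,
                "planted_hr": planted,
                "recovered_hr": row["hr"],
                "ci_low": row["ci_low"],
                "ci_high": row["ci_high"],
                "covers": bool(row["ci_low"] <= planted <= row["ci_high"]),
            }
        )
    return pd.DataFrame(rows)


def _pipeline_group_indicator(df: pd.DataFrame, group: Mapping[str, str]) -> np.ndarray:
    """Group membership judged from *classified* (not generator-true) labels."""
    colmap = {
        "cen": "cen_class",
        "tel": "tel_class",
        "cen_subtype": "cen_b_subtype",
    }
    mask = np.ones(len(df), dtype=bool)
    for key, value in group.items():
        mask &= (df[colmap[key]] == value).to_numpy()
    return mask
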