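"""End-to-end orchestration: cohort classification, frequency tables and
association reports.

Ties the other modules together the way a registry analysis is run:
classify every donor genotype, tabulate diplotype frequencies with
marginals, and fit the three endpoint models (cause-specific Cox for
relapse with non-relapse death censored, Cox for the event-free-survival
composite, cause-specific Cox for non-relapse mortality with relapse
censored) for each classifier and patient subset, producing one result
row per classifier level and endpoint.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype import classify_diplotype, parse_genotype_table
from .survival import CoxResult, coxph_cause_specific

__all__ = [
    "classify_cohort",
    "FrequencyTable",
    "diplotype_frequency_table",
    "ClassifierSpec",
    "run_association_analysis",
    "report_writer",
]

log = logging.getLogger("kirpipe")

ENDPOINTS = (("relapse_CIR", 1, False), ("EFS", None, True), ("NRM", 2, False))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed frequency tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_cohort(genotype_table, rules=None) -> pd.DataFrame:
    """Classify every donor of a genotype table (TSV path or DataFrame).

    Returns one row per donor: donor_id, cen_class, tel_class,
    cen_b_subtype, b_motif_count, cooley_category, is_double_homozygous,
    flags.  Duplicate gene-content rows are classified once and the
    labels broadcast back, so large cohorts with few distinct patterns
    classify quickly.
    """
    if isinstance(genotype_table, pd.DataFrame):
        table = genotype_table
        genotypes = None
    else:  # path or open file-like
        genotypes = parse_genotype_table(genotype_table)
        table = None

    if table is not None:
        value_cols = [c for c in table.columns if c != "donor_id"]
        unique = table[value_cols].drop_duplicates()
        unique.insert(0, "donor_id", [f"U{i}" for i in range(len(unique))])
        import io

        buf = io.StringIO()
        unique.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        unique_genotypes = parse_genotype_table(buf)
        label_rows = [_label_row(g, rules) for g in unique_genotypes]
        labels = pd.DataFrame(label_rows).drop(columns=["donor_id"])
        labels.index = pd.MultiIndex.from_frame(
            unique[value_cols].astype(str).fillna("")
        )
        keys = pd.MultiIndex.from_frame(table[value_cols].astype(str).fillna(""))
        out = labels.loc[keys].reset_index(drop=True)
        out.insert(0, "donor_id", table["donor_id"].to_numpy())
        return out
    return pd.DataFrame([_label_row(g, rules) for g in genotypes])


def _label_row(g, rules) -> dict:
    cls = classify_diplotype(g, rules)
    return {
        "donor_id": g.donor_id,
        "cen_class": cls.cen.genotype_class.value,
        "tel_class": cls.tel.genotype_class.value,
        "cen_b_subtype": cls.cen.cen_b_subtype.value,
        "b_motif_count": cls.b_motif_count,
        "cooley_category": cls.cooley_category.value,
        "is_double_homozygous": cls.is_double_homozygous,
        "flags": ";".join(cls.warnings),
    }


@dataclass
class FrequencyTable:
    """3x3 cen x tel diplotype frequency table with marginals.

    Percentages use the classified total as denominator, rounded half-up
    to one decimal.  ``double_homozygous`` sums the four corner cells
    (both regions homozygous); ``either_homozygous`` is the classified
    total minus the center (cen A/B - tel A/B) cell.
    """

    counts: pd.DataFrame  # rows cen AA/AB/BB + Sum, cols tel AA/AB/BB + Sum
    percents: pd.DataFrame
    unclassified: int
    total_classified: int
    double_homozygous: int
    either_homozygous: int

    def to_tsv(self, path: str | Path) -> None:
        merged = self.counts.astype(str).copy()
        for r in merged.index:
            for c in merged.columns:
                merged.loc[r, c] = (
                    f"{self.percents.loc[r, c]}% ({self.counts.loc[r, c]})"
                )
        merged.to_csv(path, sep="\t")


def diplotype_frequency_table(labels: pd.DataFrame) -> FrequencyTable:
    """Tabulate classified cen x tel diplotype frequencies of a cohort.

    ``labels`` needs cen_class and tel_class columns (as produced by
    :func:`classify_cohort`); donors with either region unclassifiable
    count only toward ``unclassified``.
    """
    classes = ("AA", "AB", "BB")
    classified = labels[
        labels["cen_class"].isin(classes) & labels["tel_class"].isin(classes)
    ]
    unclassified = len(labels) - len(classified)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    if len(classified):
        ct = pd.crosstab(classified["cen_class"], classified["tel_class"])
        counts = counts.add(ct.reindex(index=classes, columns=classes, fill_value=0),
                            fill_value=0).astype(int)
    total = int(counts.to_numpy().sum())
    counts.loc["Sum"] = counts.sum(axis=0)
    counts["Sum"] = counts.sum(axis=1)
    denom = max(total, 1)
    percents = counts.map(lambda v: round_half_up(100.0 * v / denom, 1))
    corners = int(
        counts.loc["AA", "AA"] + counts.loc["AA", "BB"]
        + counts.loc["BB", "AA"] + counts.loc["BB", "BB"]
    )
    either = total - int(counts.loc["AB", "AB"])
    return FrequencyTable(
        counts=counts,
        percents=percents,
        unclassified=unclassified,
        total_classified=total,
        double_homozygous=corners,
        either_homozygous=either,
    )


@dataclass
class ClassifierSpec:
    """One classifier to associate with the endpoints.

    ``column`` names the level column in the cohort frame; ``subset``
    optionally restricts to a patient subset (mapping column -> required
    value, e.g. ``{"c_group": "C1C1"}``); ``reference`` fixes the
    baseline level (default: most frequent); ``continuous`` models the
    column per unit instead of by level.
    """

    name: str
    column: str
    reference: str | None = None
    subset: Mapping[str, object] | None = None
    continuous: bool = False
    exclude_levels: tuple = (
        "unknown", "unclassifiable", "unclassified", "undetermined", "",
    )


def run_association_analysis(
    cohort: pd.DataFrame,
    specs: Sequence[ClassifierSpec],
    adjustment: Sequence[str] = (),
    strata: Sequence[str] | None = None,
    duration_col: str = "time_months",
    cause_col: str = "cause",
) -> pd.DataFrame:
    """Fit the three endpoint models for every classifier spec.

    Returns rows shaped like a published association table: classifier,
    level, endpoint, N, percent, HR, CI bounds and Wald p (reference
    levels carry HR 1 with empty CI).  No multiplicity adjustment is
    applied (each Wald p is reported as-is; this is logged).
    """
    log.info("association analysis: no multiple-testing adjustment applied")
    results: list[dict] = []
    for spec in specs:
        sub = cohort
        if spec.subset:
            for col, value in spec.subset.items():
                sub = sub[sub[col] == value]
        if sub.empty:
            log.warning("spec %s skipped: empty subset", spec.name)
            continue
        col = sub[spec.column]
        if not spec.continuous:
            keep = col.notna() & ~col.astype(str).isin(spec.exclude_levels)
            n_excl = int((~keep).sum())
            if n_excl:
                log.info("spec %s: excluded %d records with unknown level",
                         spec.name, n_excl)
            sub = sub[keep]
            levels = sub[spec.column].astype(str)
            uniq = levels.value_counts()
            if len(uniq) < 2:
                log.warning("spec %s skipped: single level", spec.name)
                continue
            ref = spec.reference or uniq.index[0]
            sub = sub.assign(
                __cls=pd.Categorical(
                    levels, categories=[ref] + [l for l in sorted(uniq.index) if l != ref]
                )
            )
            model_col = "__cls"
        else:
            sub = sub[col.notna()]
            sub = sub.assign(__cls=sub[spec.column].astype(float))
            model_col = "__cls"

        n_subset = len(sub)
        for endpoint, cause, composite in ENDPOINTS:
            try:
                fit = coxph_cause_specific(
                    sub,
                    [model_col, *adjustment],
                    cause=cause if cause is not None else 1,
                    duration_col=duration_col,
                    cause_col=cause_col,
                    strata=list(strata or []),
                    composite=composite,
                )
            except ValueError as exc:
                log.warning("spec %s endpoint %s failed: %s", spec.name, endpoint, exc)
                continue
            if spec.continuous:
                row = fit.row("__cls")
                results.append(
                    {
                        "classifier": spec.name,
                        "level": "(cont.)",
                        "endpoint": endpoint,
                        "n": n_subset,
                        "percent": 100.0,
                        "hr": row["hr"],
                        "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"],
                        "p": row["p"],
                        "converged": fit.converged,
                    }
                )
            else:
                cats = sub["__cls"].cat.categories
                for level in cats:
                    n_level = int((sub["__cls"] == level).sum())
                    base = {
                        "classifier": spec.name,
                        "level": str(level),
                        "endpoint": endpoint,
                        "n": n_level,
                        "percent": round_half_up(100.0 * n_level / n_subset, 1),
                        "converged": fit.converged,
                    }
                    if level == cats[0]:
                        base.update(hr=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan)
                    else:
                        name = f"__cls[{level}]"
                        match = fit.summary[fit.summary["covariate"] == name]
                        if match.empty:
                            continue
                        r = match.iloc[0]
                        base.update(
                            hr=r["hr"], ci_low=r["ci_low"],
                            ci_high=r["ci_high"], p=r["p"],
                        )
                    results.append(base)
    return pd.DataFrame(results)


def report_writer(
    results: pd.DataFrame,
    outdir: str | Path,
    metadata: Mapping[str, object] | None = None,
    frequency_table: FrequencyTable | None = None,
) -> dict[str, Path]:
    """Write associations.tsv, report.md and run.json into ``outdir``.

    The markdown report mirrors the usual association-table layout (one
    group header per classifier, one row per level with the three
    endpoint columns); run.json records metadata such as config checksums
    and seeds.  An empty result set produces a header-only TSV with a
    warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tsv = outdir / "associations.tsv"
    columns = ["classifier", "level", "endpoint", "n", "percent",
               "hr", "ci_low", "ci_high", "p", "converged"]
    if results.empty:
        log.warning("empty result set: writing header-only associations.tsv")
        pd.DataFrame(columns=columns).to_csv(tsv, sep="\t", index=False)
    else:
        results[columns].to_csv(tsv, sep="\t", index=False)
    paths["associations"] = tsv

    md = [
        "# Association report",
        "",
        "| Classifier / level | N | % | Relapse HR (95%-CI), p | EFS HR (95%-CI), p | NRM HR (95%-CI), p |",
        "|---|---|---|---|---|---|",
    ]
    if not results.empty:
        def _cell(rows, endpoint):
            r = rows[rows["endpoint"] == endpoint]
            if r.empty:
                return ""
            r = r.iloc[0]
            if np.isnan(r.get("p", np.nan)) and r["hr"] == 1.0:
                return "1 (ref)"
            return f"{r['hr']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f}), p={r['p']:.2g}"

        for classifier in results["classifier"].unique():
            block = results[results["classifier"] == classifier]
            md.append(f"| **{classifier}** | | | | | |")
            for level in block["level"].unique():
                rows = block[block["level"] == level]
                n = int(rows["n"].iloc[0])
                pct = rows["percent"].iloc[0]
                md.append(
                    f"| {level} | {n} | {pct} | "
                    f"{_cell(rows, 'relapse_CIR')} | {_cell(rows, 'EFS')} | "
                    f"{_cell(rows, 'NRM')} |"
                )
    if frequency_table is not None:
        md += ["", "## Diplotype frequencies", ""]
        ft = frequency_table
        md.append("| cen \\ tel | " + " | ".join(ft.counts.columns) + " |")
        md.append("|---" * (len(ft.counts.columns) + 1) + "|")
        for r in ft.counts.index:
            cells = [
                f"{ft.percents.loc[r, c]}% ({ft.counts.loc[r, c]})"
                for c in ft.counts.columns
            ]
            md.append(f"| {r} | " + " | ".join(cells) + " |")
        md.append(f"\n{ft.unclassified} genotypes unclassifiable; "
                  f"{ft.double_homozygous} donors homozygous for both regions; "
                  f"{ft.either_homozygous} homozygous for at least one.")
    report = outdir / "report.md"
    report.write_text("\n".join(md) + "\n")
    paths["report"] = report

    meta = dict(metadata or {})
    meta.setdefault("generated_at", datetime.datetime.now().isoformat())
    meta.setdefault("n_result_rows", int(len(results)))
    run_json = outdir / "run.json"
    run_json.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    paths["metadata"] = run_json

    if frequency_table is not None:
        freq = outdir / "frequencies.tsv"
        frequency_table.to_tsv(freq)
        paths["frequencies"] = freq
    return paths
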