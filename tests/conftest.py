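"""Shared fixtures: genotype builders and small synthetic inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kirpipe.genotype import (
    DonorKirGenotype,
    FRAMEWORK_GENES,
    GeneState,
    GeneStatus,
    KIR_LOCI,
)

FW = set(FRAMEWORK_GENES)

# canonical per-motif gene contents used to assemble test genotypes
CEN_A = {"2DL3", "2DP1", "2DL1"}
CEN_B01 = {"2DS2", "2DL2", "2DL5", "2DS3", "2DP1", "2DL1"}
CEN_B02 = {"2DS2", "2DL2"}
TEL_A = {"3DL1", "2DS4"}
TEL_B = {"3DS1", "2DL5", "2DS5", "2DS1"}


def make_genotype(
    present: set[str],
    alleles: dict[str, tuple[str, ...]] | None = None,
    copy_numbers: dict[str, int] | None = None,
    unknown: set[str] | None = None,
    donor_id: str = "D",
) -> DonorKirGenotype:
    genes: dict[str, GeneStatus] = {}
    alleles = alleles or {}
    copy_numbers = copy_numbers or {}
    unknown = unknown or set()
    for locus in KIR_LOCI:
        if locus in unknown:
            genes[locus] = GeneStatus(GeneState.UNKNOWN)
        elif locus in present or locus in alleles:
            genes[locus] = GeneStatus(
                GeneState.PRESENT,
                tuple(alleles.get(locus, ())),
                copy_numbers.get(locus),
            )
        else:
            genes[locus] = GeneStatus(GeneState.ABSENT)
    return DonorKirGenotype(donor_id, genes)


@pytest.fixture
def geno_factory():
    return make_genotype


@pytest.fixture
def table3_labels() -> pd.DataFrame:
    """A label frame encoding the published 3x3 diplotype cell counts."""
    cells = {
        ("AA", "AA"): 1616, ("AA", "AB"): 709, ("AA", "BB"): 71,
        ("AB", "AA"): 1170, ("AB", "AB"): 809, ("AB", "BB"): 109,
        ("BB", "AA"): 237, ("BB", "AB"): 211, ("BB", "BB"): 43,
    }
    rows = []
    for (cen, tel), count in cells.items():
        rows += [{"cen_class": cen, "tel_class": tel}] * count
    rows += [{"cen_class": "unclassifiable", "tel_class": "unclassifiable"}] * 42
    df = pd.DataFrame(rows)
    df.insert(0, "donor_id", [f"D{i}" for i in range(len(df))])
    return df


@pytest.fixture
def competing_risks_sample():
    """A small tie-free competing-risks dataset with two groups."""
    rng = np.random.default_rng(2024)
    n = 60
    g = rng.integers(0, 2, n)
    t1 = rng.exponential(1 / 0.30, n)
    t2 = rng.exponential(1 / 0.20, n)
    cens = rng.exponential(1 / 0.15, n)
    t = np.minimum.reduce([t1, t2, cens])
    cause = np.where(t == t1, 1, np.where(t == t2, 2, 0))
    return t, cause, g
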