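"""Shared fixtures: small hand-built datasets and simulator shortcuts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohfst.io import GenotypeDataset, MISSING


def make_dataset(calls, positions=None, chromosomes=None, populations=None,
                 allele_a="A", allele_b="G"):
    """Build a GenotypeDataset from a plain nested list of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_mk = calls.shape
    if positions is None:
        positions = [100_000 * (j + 1) for j in range(n_mk)]
    if chromosomes is None:
        chromosomes = ["1"] * n_mk
    markers = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(n_mk)],
            "chromosome": [str(c) for c in chromosomes],
            "position_bp": positions,
            "allele_a": [allele_a] * n_mk,
            "allele_b": [allele_b] * n_mk,
        }
    )
    if populations is None:
        populations = ["popA"] * n_ind
    individuals = pd.DataFrame(
        {
            "individual_id": [f"ind{i + 1}" for i in range(n_ind)],
            "population": populations,
        }
    )
    return GenotypeDataset(markers=markers, individuals=individuals, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_ped_map(tmp_path):
    """2 individuals x 3 markers; one '0 0' pair; allele_b=G at snp2."""
    map_text = "1\tsnp1\t0\t1000\n1\tsnp2\t0\t2000\n1\tsnp3\t0\t3000\n"
    ped_text = (
        "famA ind1 0 0 0 -9 A A A A C C\n"
        "famA ind2 0 0 0 -9 A A A G 0 0\n"
    )
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp


MISSING = MISSING
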