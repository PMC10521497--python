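"""ROH incidence tracks and hotspot (ROH island) calling.

For each population, the incidence of a SNP is the share of that
population's individuals with at least one ROH covering the SNP's position
(segment endpoints count as covered: they are member SNPs by construction).
A hotspot is a maximal run of consecutive QC-retained SNPs on one
chromosome whose incidence reaches the threshold (default 40%, inclusive
comparison) over at least ``min_snps`` consecutive SNPs (default 20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset, ROHSegment
from .roh import _chromosome_blocks


@dataclass
class IncidenceTrack:
    """Per-marker ROH incidence for one population, aligned to the map."""

    population: str
    values: np.ndarray  # fraction in [0, 1], one per marker
    n_individuals: int


@dataclass
class HotspotRegion:
    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float


def incidence(
    segments: list[ROHSegment], ds: GenotypeDataset, population: str
) -> IncidenceTrack:
    """Fraction of a population's individuals whose ROH cover each marker."""
    mask = (ds.individuals["population"] == population).to_numpy()
    n_pop = int(mask.sum())
    if n_pop == 0:
        raise ValueError(f"population {population!r} has no individuals")
    pop_ids = set(ds.individuals.loc[mask, "individual_id"].astype(str))

    chrom = ds.markers["chromosome"].astype(str).to_numpy()
    pos = ds.markers["position_bp"].to_numpy(dtype=np.int64)
    blocks = {c: b for c, b in _chromosome_blocks(ds)}

    covered_count = np.zeros(ds.n_markers, dtype=np.int64)
    by_ind: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        if seg.population == population and seg.individual_id in pop_ids:
            by_ind.setdefault(seg.individual_id, []).append(seg)

    for segs in by_ind.values():
        covered = np.zeros(ds.n_markers, dtype=bool)
        for seg in segs:
            block = blocks.get(seg.chromosome)
            if block is None:
                continue
            bp = pos[block]
            lo = int(np.searchsorted(bp, seg.start_bp, side="left"))
            hi = int(np.searchsorted(bp, seg.end_bp, side="right"))
            covered[block[lo:hi]] = True
        covered_count += covered

    track = covered_count / n_pop
    assert chrom.shape == track.shape
    return IncidenceTrack(population=population, values=track, n_individuals=n_pop)


def call_hotspots(
    track: IncidenceTrack,
    ds: GenotypeDataset,
    threshold: float = 0.40,
    min_snps: int = 20,
    inclusive: bool = True,
) -> list[HotspotRegion]:
    """Maximal above-threshold runs of consecutive SNPs within chromosomes.

    ``inclusive`` selects ``>= threshold`` (default, conservative reading of
    "40% of ROH occurrence"); ``False`` selects a strict ``>``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    above = (
        track.values >= threshold if inclusive else track.values > threshold
    )
    pos = ds.markers["position_bp"].to_numpy(dtype=np.int64)
    regions: list[HotspotRegion] = []
    for chrom, block in _chromosome_blocks(ds):
        a = above[block]
        n = a.size
        j = 0
        while j < n:
            if not a[j]:
                j += 1
                continue
            k = j
            while k < n and a[k]:
                k += 1
            if k - j >= min_snps:
                members = block[j:k]
                regions.append(
                    HotspotRegion(
                        population=track.population,
                        chromosome=str(chrom),
                        start_bp=int(pos[members[0]]),
                        end_bp=int(pos[members[-1]]),
                        n_snps=int(k - j),
                        peak_incidence=float(track.values[members].max()),
                    )
                )
            j = k
    return regions


def manhattan_table(track: IncidenceTrack, ds: GenotypeDataset) -> pd.DataFrame:
    """Plotting-ready per-marker table (chr, bp, incidence in percent)."""
    return pd.DataFrame(
        {
            "chr": ds.markers["chromosome"].astype(str),
            "position_bp": ds.markers["position_bp"],
            "incidence_pct": track.values * 100.0,
        }
    )


def hotspot_frame(regions: list[HotspotRegion]) -> pd.DataFrame:
    """Table-2-shaped hotspot table (breed, chr, n_snps, from, to, peak %)."""
    return pd.DataFrame(
        [
            {
                "population": r.population,
                "chr": r.chromosome,
                "n_snps": r.n_snps,
                "from_bp": r.start_bp,
                "to_bp": r.end_bp,
                "peak_incidence_pct": r.peak_incidence * 100.0,
            }
            for r in regions
        ],
        columns=[
            "population",
            "chr",
            "n_snps",
            "from_bp",
            "to_bp",
            "peak_incidence_pct",
        ],
    )
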