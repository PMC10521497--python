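"""Consecutive-runs ROH detection, length classes, breed summaries, F_ROH.

A run of homozygosity is detected per individual and chromosome by a single
left-to-right pass over the SNP map (no sliding window).  A qualifying run

* starts and ends on a homozygous, non-missing SNP,
* contains at most ``max_het`` heterozygous and ``max_missing`` missing
  calls,
* has every gap between consecutive member SNPs at most ``max_gap_bp``,
* spans at least ``min_snps`` SNPs and ``min_length_bp`` base pairs
  (``length = end_bp - start_bp``).

The scan reports the qualifying run with the leftmost feasible start and,
for that start, the maximal end, then continues after it; reported runs on
one chromosome therefore never overlap, and each is maximal at its start.
Defaults (20 SNPs, 250 kb, 1 Mb gap, 1 heterozygote, 1 missing) are the
standard consecutive-runs settings for ~50K livestock arrays.

F_ROH is the fraction of the autosomal genome covered by an individual's
ROH: ``F_ROH = L_ROH / L_auto`` with ``L_auto`` defaulting to 2.46 Gb, the
SNP-covered autosomal span of the goat genome.  Per-chromosome F_ROH uses
the SNP-covered span of each chromosome as denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, ROHSegment, chromosome_sort_key

#: Total SNP-covered autosomal length of the goat genome (bp).
GOAT_L_AUTO_BP: int = 2_460_000_000

#: Length-class boundaries in Mb: [0,2), [2,4), [4,8), [8,16), [16, inf).
DEFAULT_CLASS_BOUNDARIES_MB: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)


@dataclass
class ROHParams:
    """Consecutive-runs detection criteria."""

    min_snps: int = 20
    min_length_bp: int = 250_000
    max_gap_bp: int = 1_000_000
    max_het: int = 1
    max_missing: int = 1

    def __post_init__(self) -> None:
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        for name in ("min_length_bp", "max_gap_bp", "max_het", "max_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _scan_chromosome(
    g: np.ndarray, pos: np.ndarray, p: ROHParams
) -> list[tuple[int, int]]:
    """Two-pointer scan of one individual's calls on one chromosome.

    Returns (start_index, end_index) pairs of reported runs.
    """
    n = g.size
    out: list[tuple[int, int]] = []
    s = 0
    e = 0  # candidate window is [s, e)
    het = 0
    miss = 0
    is_hom = (g == 0) | (g == 2)
    while s < n:
        if not is_hom[s]:
            if s < e:
                het -= g[s] == 1
                miss -= g[s] == MISSING
            s += 1
            continue
        if e <= s:
            e = s
            het = 0
            miss = 0
        while e < n:
            if e > s and pos[e] - pos[e - 1] > p.max_gap_bp:
                break
            nh = het + (g[e] == 1)
            nm = miss + (g[e] == MISSING)
            if nh > p.max_het or nm > p.max_missing:
                break
            het, miss = nh, nm
            e += 1
        t = e - 1
        while t > s and not is_hom[t]:
            t -= 1
        if (
            t - s + 1 >= p.min_snps
            and pos[t] - pos[s] >= p.min_length_bp
        ):
            out.append((s, t))
            while s <= t:
                if s < e:
                    het -= g[s] == 1
                    miss -= g[s] == MISSING
                s += 1
        else:
            if s < e:
                het -= g[s] == 1
                miss -= g[s] == MISSING
            s += 1
    return out


def _chromosome_blocks(ds: GenotypeDataset) -> list[tuple[str, np.ndarray]]:
    """Contiguous marker-index blocks per chromosome, validated sorted."""
    chrom = ds.markers["chromosome"].astype(str).to_numpy()
    pos = ds.markers["position_bp"].to_numpy()
    blocks: list[tuple[str, np.ndarray]] = []
    seen: set[str] = set()
    j = 0
    n = len(chrom)
    while j < n:
        c = chrom[j]
        if c in seen:
            raise ValueError(
                f"markers are not sorted: chromosome {c!r} appears in "
                "non-contiguous blocks"
            )
        seen.add(c)
        k = j
        while k < n and chrom[k] == c:
            k += 1
        block = np.arange(j, k)
        d = np.diff(pos[block])
        if (d < 0).any():
            raise ValueError(
                f"markers on chromosome {c!r} are not position-sorted"
            )
        blocks.append((c, block))
        j = k
    return blocks


def detect_roh(
    ds: GenotypeDataset, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Detect runs of homozygosity for every individual in the dataset."""
    params = params or ROHParams()
    blocks = _chromosome_blocks(ds)
    pos_all = ds.markers["position_bp"].to_numpy(dtype=np.int64)
    segments: list[ROHSegment] = []
    iids = ds.individuals["individual_id"].to_numpy()
    pops = ds.individuals["population"].to_numpy()
    for i in range(ds.n_individuals):
        row = ds.calls[i]
        for chrom, block in blocks:
            g = row[block]
            pos = pos_all[block]
            for s, t in _scan_chromosome(g, pos, params):
                segments.append(
                    ROHSegment(
                        individual_id=str(iids[i]),
                        population=str(pops[i]),
                        chromosome=str(chrom),
                        start_bp=int(pos[s]),
                        end_bp=int(pos[t]),
                        n_snps=int(t - s + 1),
                    )
                )
    return segments


# ---------------------------------------------------------------------------
# Length classes
# ---------------------------------------------------------------------------

def class_labels(
    boundaries_mb: tuple[float, ...] = DEFAULT_CLASS_BOUNDARIES_MB,
) -> list[str]:
    bounds = list(boundaries_mb)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("class boundaries must be strictly increasing")
    labels = [f"0-{bounds[0]:g} Mb"]
    labels += [
        f"{lo:g}-{hi:g} Mb" for lo, hi in zip(bounds, bounds[1:])
    ]
    labels.append(f">{bounds[-1]:g} Mb")
    return labels


def classify_lengths(
    segments: list[ROHSegment],
    boundaries_mb: tuple[float, ...] = DEFAULT_CLASS_BOUNDARIES_MB,
) -> dict[str, int]:
    """Count segments per half-open length class [lo, hi) in Mb."""
    labels = class_labels(boundaries_mb)
    bounds_bp = [b * 1e6 for b in boundaries_mb]
    counts: Counter[str] = Counter({lab: 0 for lab in labels})
    for seg in segments:
        k = int(np.searchsorted(bounds_bp, seg.length_bp, side="right"))
        counts[labels[k]] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# Per-breed summaries
# ---------------------------------------------------------------------------

@dataclass
class BreedROHSummary:
    population: str
    n_individuals: int
    total_roh: int
    mean_count: float
    min_count: int
    max_count: int
    mean_total_length_mb: float
    min_total_length_mb: float
    max_total_length_mb: float
    class_counts: dict[str, int] = field(default_factory=dict)
    per_chromosome_counts: dict[str, int] = field(default_factory=dict)


def summarize_by_breed(
    segments: list[ROHSegment],
    ds: GenotypeDataset,
    boundaries_mb: tuple[float, ...] = DEFAULT_CLASS_BOUNDARIES_MB,
) -> list[BreedROHSummary]:
    """Per-population ROH count/length statistics (Table-1-shaped).

    Individuals with no segments contribute zero counts and lengths to the
    means; populations with zero individuals are skipped.
    """
    by_pop_ind: dict[str, dict[str, list[ROHSegment]]] = {}
    for pop in ds.populations():
        mask = ds.individuals["population"] == pop
        by_pop_ind[pop] = {
            str(iid): []
            for iid in ds.individuals.loc[mask, "individual_id"]
        }
    for seg in segments:
        by_pop_ind.setdefault(seg.population, {}).setdefault(
            seg.individual_id, []
        ).append(seg)

    out: list[BreedROHSummary] = []
    for pop, per_ind in by_pop_ind.items():
        if not per_ind:
            continue
        counts = np.array([len(v) for v in per_ind.values()])
        lengths_mb = np.array(
            [sum(s.length_bp for s in v) / 1e6 for v in per_ind.values()]
        )
        pop_segments = [s for v in per_ind.values() for s in v]
        chrom_counts = Counter(s.chromosome for s in pop_segments)
        out.append(
            BreedROHSummary(
                population=pop,
                n_individuals=len(per_ind),
                total_roh=int(counts.sum()),
                mean_count=float(counts.mean()),
                min_count=int(counts.min()),
                max_count=int(counts.max()),
                mean_total_length_mb=float(lengths_mb.mean()),
                min_total_length_mb=float(lengths_mb.min()),
                max_total_length_mb=float(lengths_mb.max()),
                class_counts=classify_lengths(pop_segments, boundaries_mb),
                per_chromosome_counts=dict(
                    sorted(
                        chrom_counts.items(),
                        key=lambda kv: chromosome_sort_key(kv[0]),
                    )
                ),
            )
        )
    return out


def breed_summary_frame(summaries: list[BreedROHSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "population": s.population,
            "n_individuals": s.n_individuals,
            "total_roh": s.total_roh,
            "mean_count": s.mean_count,
            "min_count": s.min_count,
            "max_count": s.max_count,
            "mean_total_length_mb": s.mean_total_length_mb,
            "min_total_length_mb": s.min_total_length_mb,
            "max_total_length_mb": s.max_total_length_mb,
        }
        row.update({f"class {k}": v for k, v in s.class_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------

@dataclass
class FrohResult:
    individual_id: str
    froh_genome: float
    froh_per_chromosome: dict[str, float]
    l_roh_bp: int
    l_auto_bp: int = GOAT_L_AUTO_BP


def chromosome_spans(ds: GenotypeDataset) -> dict[str, int]:
    """SNP-covered span (last - first position, bp) of each chromosome."""
    spans: dict[str, int] = {}
    for chrom, grp in ds.markers.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        spans[str(chrom)] = int(pos.max() - pos.min())
    return spans


def compute_froh(
    segments: list[ROHSegment],
    l_auto_bp: int = GOAT_L_AUTO_BP,
    chrom_spans: dict[str, int] | None = None,
    individual_id: str | None = None,
) -> FrohResult:
    """Genomic and per-chromosome inbreeding of one individual.

    ``segments`` must all belong to the same individual.  The genome-wide
    coefficient is the summed segment length over ``l_auto_bp``; the
    per-chromosome coefficient divides by the SNP-covered span of each
    chromosome in ``chrom_spans``.
    """
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    ids = {s.individual_id for s in segments}
    if len(ids) > 1:
        raise ValueError(f"segments belong to several individuals: {ids}")
    if individual_id is None:
        individual_id = next(iter(ids)) if ids else ""

    l_roh = sum(s.length_bp for s in segments)
    per_chrom: dict[str, float] = {}
    if chrom_spans is not None:
        per_chrom = {c: 0.0 for c in chrom_spans}
        for s in segments:
            if s.chromosome not in chrom_spans:
                raise ValueError(
                    f"segment on chromosome {s.chromosome!r} has no span"
                )
        for s in segments:
            span = chrom_spans[s.chromosome]
            if span > 0:
                per_chrom[s.chromosome] += s.length_bp / span
    return FrohResult(
        individual_id=individual_id,
        froh_genome=l_roh / l_auto_bp,
        froh_per_chromosome=per_chrom,
        l_roh_bp=int(l_roh),
        l_auto_bp=int(l_auto_bp),
    )


def froh_table(
    segments: list[ROHSegment],
    ds: GenotypeDataset,
    l_auto_bp: int = GOAT_L_AUTO_BP,
) -> pd.DataFrame:
    """Per-individual F_ROH (genome-wide and per chromosome) for a dataset."""
    spans = chromosome_spans(ds)
    by_ind: dict[str, list[ROHSegment]] = {
        str(iid): [] for iid in ds.individuals["individual_id"]
    }
    for seg in segments:
        by_ind.setdefault(seg.individual_id, []).append(seg)
    chroms = sorted(spans, key=chromosome_sort_key)
    rows = []
    pops = dict(
        zip(
            ds.individuals["individual_id"].astype(str),
            ds.individuals["population"].astype(str),
        )
    )
    for iid, segs in by_ind.items():
        res = compute_froh(segs, l_auto_bp, spans, individual_id=iid)
        row = {
            "individual_id": iid,
            "population": pops.get(iid, ""),
            "l_roh_bp": res.l_roh_bp,
            "froh_genome": res.froh_genome,
        }
        row.update(
            {f"froh_chr{c}": res.froh_per_chromosome.get(c, 0.0) for c in chroms}
        )
        rows.append(row)
    return pd.DataFrame(rows)
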