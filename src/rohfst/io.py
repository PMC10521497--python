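"""Genotype data model and plain-text file I/O.

The in-memory currency of the whole pipeline is :class:`GenotypeDataset`:
an individuals x markers matrix of allele-B dosages (0/1/2, ``MISSING`` = -1)
plus a marker map (chromosome, 1-based bp position) and a population label
per individual.  Datasets are read from and written to the whitespace-
delimited PED/MAP text dialect; ROH segments and genomic intervals are
serialised as TSV and BED.

Internal coordinates are 1-based inclusive (MAP convention); BED export
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in ``GenotypeDataset.calls``.
MISSING: int = -1

#: Alphabet allowed for alleles in PED files ('0' encodes a missing allele).
VALID_ALLELES = frozenset("ACGT0")

#: Chromosome labels treated as autosomal (goat: 29 autosomes).
AUTOSOMES = frozenset(str(c) for c in range(1, 30))

MARKER_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
INDIVIDUAL_COLUMNS = ["individual_id", "population"]


class PedMapError(ValueError):
    """Raised for malformed PED/MAP input."""


def chromosome_sort_key(label: str) -> tuple[int, int, str]:
    """Sort key placing numeric chromosomes first, in numeric order."""
    s = str(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass
class ROHSegment:
    """One homozygous run in one individual.

    Coordinates are 1-based inclusive positions of the first and last member
    SNP; ``length_bp = end_bp - start_bp`` (difference convention, matching
    how interval sizes are quoted in Mb elsewhere in the pipeline).
    """

    individual_id: str
    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"ROH segment start {self.start_bp} > end {self.end_bp}"
            )
        if self.n_snps < 1:
            raise ValueError("ROH segment must contain at least one SNP")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes for several populations.

    Attributes
    ----------
    markers : pandas.DataFrame
        Columns ``snp_id, chromosome, position_bp, allele_a, allele_b``;
        ordered by chromosome then position.  ``allele_b`` is the
        dosage-counted allele (second distinct allele observed in file order
        when read from PED); a monomorphic marker has ``allele_b == '0'``.
    individuals : pandas.DataFrame
        Columns ``individual_id, population``.
    calls : numpy.ndarray
        ``int8`` matrix of shape (n_individuals, n_markers) holding counts
        of ``allele_b`` (0, 1, 2) or ``MISSING``.
    """

    markers: pd.DataFrame
    individuals: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def validate(self) -> None:
        if list(self.markers.columns) != MARKER_COLUMNS:
            raise ValueError(f"marker table must have columns {MARKER_COLUMNS}")
        if list(self.individuals.columns) != INDIVIDUAL_COLUMNS:
            raise ValueError(
                f"individual table must have columns {INDIVIDUAL_COLUMNS}"
            )
        if self.calls.shape != (self.n_individuals, self.n_markers):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_individuals} individuals x {self.n_markers} markers"
            )
        ok = (self.calls == MISSING) | (
            (self.calls >= 0) & (self.calls <= 2)
        )
        if not ok.all():
            raise ValueError("calls must be in {0,1,2} or MISSING")
        if (self.markers["position_bp"].to_numpy() < 0).any():
            raise ValueError("marker positions must be >= 0")

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.individuals["population"]))

    def individual_index(self, individual_id: str) -> int:
        idx = np.flatnonzero(
            self.individuals["individual_id"].to_numpy() == individual_id
        )
        if idx.size == 0:
            raise KeyError(f"unknown individual {individual_id!r}")
        return int(idx[0])

    def subset(
        self,
        individual_idx: Sequence[int] | np.ndarray | None = None,
        marker_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        ii = (
            np.arange(self.n_individuals)
            if individual_idx is None
            else np.asarray(individual_idx)
        )
        mi = (
            np.arange(self.n_markers)
            if marker_idx is None
            else np.asarray(marker_idx)
        )
        return GenotypeDataset(
            markers=self.markers.iloc[mi].reset_index(drop=True),
            individuals=self.individuals.iloc[ii].reset_index(drop=True),
            calls=self.calls[np.ix_(ii, mi)].copy(),
        )

    def sorted_by_map(self) -> "GenotypeDataset":
        """Return a copy with markers sorted by (chromosome, position)."""
        order = sorted(
            range(self.n_markers),
            key=lambda j: (
                chromosome_sort_key(self.markers["chromosome"].iat[j]),
                int(self.markers["position_bp"].iat[j]),
            ),
        )
        return self.subset(marker_idx=order)

    def swap_alleles(self, marker_idx: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        """Swap allele_a/allele_b orientation at the given markers (c -> 2-c)."""
        mi = np.asarray(marker_idx, dtype=int)
        markers = self.markers.copy()
        a = markers.loc[mi, "allele_a"].copy()
        markers.loc[mi, "allele_a"] = markers.loc[mi, "allele_b"].to_numpy()
        markers.loc[mi, "allele_b"] = a.to_numpy()
        calls = self.calls.copy()
        sub = calls[:, mi]
        nonmiss = sub != MISSING
        sub[nonmiss] = 2 - sub[nonmiss]
        calls[:, mi] = sub
        return GenotypeDataset(markers=markers, individuals=self.individuals.copy(), calls=calls)

    def equals(self, other: "GenotypeDataset") -> bool:
        """Semantic equality, canonical under allele orientation.

        PED files do not record which allele is dosage-counted, so a
        write/read round trip may flip orientation at markers whose first
        observed genotype is an allele_b homozygote.  Two datasets are equal
        when maps, individuals, and unordered genotypes agree marker by
        marker.
        """
        if self.calls.shape != other.calls.shape:
            return False
        if not self.individuals.equals(other.individuals):
            return False
        m1 = self.markers[["snp_id", "chromosome", "position_bp"]]
        m2 = other.markers[["snp_id", "chromosome", "position_bp"]]
        if not m1.equals(m2):
            return False
        a1 = self.markers["allele_a"].to_numpy()
        b1 = self.markers["allele_b"].to_numpy()
        a2 = other.markers["allele_a"].to_numpy()
        b2 = other.markers["allele_b"].to_numpy()
        same = (a1 == a2) & (b1 == b2)
        flipped = (a1 == b2) & (b1 == a2)
        for j in range(self.n_markers):
            c1 = self.calls[:, j]
            c2 = other.calls[:, j]
            if same[j] and np.array_equal(c1, c2):
                continue
            # orientation may be flipped (or undetectable on monomorphic
            # markers); compare unordered genotypes
            c2f = np.where(c2 == MISSING, MISSING, 2 - c2)
            if np.array_equal(c1, c2) or np.array_equal(c1, c2f):
                continue
            return False
        return True


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def _read_map(map_path: Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise PedMapError(
                    f"{map_path}:{lineno}: MAP rows need 4 columns "
                    f"(chr, snp_id, cM, bp), got {len(fields)}"
                )
            chrom, snp_id, _cm, bp = fields
            if not snp_id:
                raise PedMapError(f"{map_path}:{lineno}: empty SNP id")
            try:
                bp_i = int(bp)
            except ValueError as exc:
                raise PedMapError(
                    f"{map_path}:{lineno}: non-integer position {bp!r}"
                ) from exc
            if bp_i < 0:
                raise PedMapError(f"{map_path}:{lineno}: negative position")
            rows.append((snp_id, chrom, bp_i))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a whitespace-delimited PED/MAP pair into a :class:`GenotypeDataset`.

    The PED family-ID column is used as the population label.  The
    dosage-counted allele (``allele_b``) at each marker is the second
    distinct non-missing allele observed in file order; ``0 0`` allele
    pairs become :data:`MISSING`.  A half-missing genotype (``A 0``) is
    rejected.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    marker_map = _read_map(map_path)
    n_markers = len(marker_map)

    meta: list[tuple[str, str]] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 6 or (len(fields) - 6) % 2 != 0:
                raise PedMapError(
                    f"{ped_path}:{lineno}: ragged PED row with "
                    f"{len(fields)} fields"
                )
            if (len(fields) - 6) // 2 != n_markers:
                raise PedMapError(
                    f"{ped_path}:{lineno}: PED row has "
                    f"{(len(fields) - 6) // 2} markers but MAP lists "
                    f"{n_markers}"
                )
            fam, iid = fields[0], fields[1]
            alleles = np.array(fields[6:], dtype="U1")
            bad = ~np.isin(alleles, sorted(VALID_ALLELES))
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise PedMapError(
                    f"{ped_path}:{lineno}: invalid allele "
                    f"{fields[6 + j]!r}"
                )
            meta.append((iid, fam))
            allele_rows.append(alleles)

    individuals = pd.DataFrame(meta, columns=INDIVIDUAL_COLUMNS)
    n_ind = len(individuals)
    if n_ind == 0:
        calls = np.empty((0, n_markers), dtype=np.int8)
        markers = marker_map.assign(allele_a="0", allele_b="0")
        return GenotypeDataset(markers=markers[MARKER_COLUMNS], individuals=individuals, calls=calls)

    al = np.vstack(allele_rows)  # (n_ind, 2 * n_markers)
    a1 = al[:, 0::2]
    a2 = al[:, 1::2]
    half = (a1 == "0") ^ (a2 == "0")
    if half.any():
        i, j = np.argwhere(half)[0]
        raise PedMapError(
            f"half-missing genotype for individual "
            f"{individuals['individual_id'].iat[i]!r} at marker "
            f"{marker_map['snp_id'].iat[j]!r} ('A 0' style pairs are not "
            "supported)"
        )

    calls = np.full((n_ind, n_markers), MISSING, dtype=np.int8)
    allele_a = np.full(n_markers, "0", dtype="U1")
    allele_b = np.full(n_markers, "0", dtype="U1")
    for j in range(n_markers):
        pair = np.empty(2 * n_ind, dtype="U1")
        pair[0::2] = a1[:, j]
        pair[1::2] = a2[:, j]
        observed = pair[pair != "0"]
        distinct = list(dict.fromkeys(observed.tolist()))
        if len(distinct) > 2:
            raise PedMapError(
                f"marker {marker_map['snp_id'].iat[j]!r} has more than two "
                f"alleles: {distinct}"
            )
        if distinct:
            allele_a[j] = distinct[0]
        if len(distinct) == 2:
            allele_b[j] = distinct[1]
        nonmiss = a1[:, j] != "0"
        dosage = (a1[:, j] == allele_b[j]).astype(np.int8) + (
            a2[:, j] == allele_b[j]
        ).astype(np.int8)
        calls[nonmiss, j] = dosage[nonmiss]

    markers = marker_map.assign(allele_a=allele_a, allele_b=allele_b)
    return GenotypeDataset(
        markers=markers[MARKER_COLUMNS], individuals=individuals, calls=calls
    )


def write_ped_map(
    ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset as a PED/MAP pair (round-trips via :func:`read_ped_map`)."""
    ds.validate()
    with open(map_path, "w") as fh:
        for row in ds.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")

    a = ds.markers["allele_a"].to_numpy(dtype="U1")
    b = ds.markers["allele_b"].to_numpy(dtype="U1")
    # b may be '0' on monomorphic markers; only dosage 0 occurs there
    geno_strings = np.empty((4, ds.n_markers), dtype=object)
    geno_strings[0] = np.char.add(np.char.add(a, " "), a)
    geno_strings[1] = np.char.add(np.char.add(a, " "), b)
    geno_strings[2] = np.char.add(np.char.add(b, " "), b)
    geno_strings[3] = "0 0"
    with open(ped_path, "w") as fh:
        for i in range(ds.n_individuals):
            iid = ds.individuals["individual_id"].iat[i]
            fam = ds.individuals["population"].iat[i]
            row = ds.calls[i]
            idx = np.where(row == MISSING, 3, row)
            geno = geno_strings[idx, np.arange(ds.n_markers)]
            fh.write(
                f"{fam} {iid} 0 0 0 -9 " + " ".join(geno.tolist()) + "\n"
            )


# ---------------------------------------------------------------------------
# Segment and interval tables
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = [
    "individual",
    "population",
    "chr",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_bp",
]


def segments_to_frame(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    rows = [
        (
            s.individual_id,
            s.population,
            s.chromosome,
            s.start_bp,
            s.end_bp,
            s.n_snps,
            s.length_bp,
        )
        for s in segments
    ]
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["population", "individual", "chr", "start_bp"],
            key=lambda col: (
                col.map(chromosome_sort_key) if col.name == "chr" else col
            ),
            kind="stable",
        ).reset_index(drop=True)
    return df


def write_segments_tsv(segments: Iterable[ROHSegment], path: str | Path) -> None:
    """Write ROH segments as a TSV table, ordered by (population, individual, chr, start)."""
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path: str | Path) -> list[ROHSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return [
        ROHSegment(
            individual_id=str(r.individual),
            population=str(r.population),
            chromosome=str(r.chr),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_snps=int(r.n_snps),
        )
        for r in df.itertuples(index=False)
    ]


def write_bed_intervals(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open).

    Conversion is ``start - 1, end``; a resulting negative coordinate is a
    validation error.
    """
    lines = []
    for chrom, start, end, name in intervals:
        if start > end:
            raise ValueError(f"interval start {start} > end {end}")
        bed_start = int(start) - 1
        if bed_start < 0:
            raise ValueError(
                f"BED start would be negative for 1-based start {start}"
            )
        lines.append(f"{chrom}\t{bed_start}\t{int(end)}\t{name}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
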