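"""Synthetic multi-population SNP-array data with known ground truth.

Differentiation follows the Balding-Nichols model: each SNP draws an
ancestral allele frequency p ~ Uniform(ancestral_freq_range); population i
with drift parameter F_i draws its own frequency from
Beta(p (1-F_i)/F_i, (1-p)(1-F_i)/F_i) (exactly p when F_i = 0), and
genotypes are Binomial(2, freq) per individual, independent across SNPs
(no linkage disequilibrium).  Under this model the expected pairwise
Weir-Cockerham theta between two populations with common drift F is F,
which gives downstream estimators a clean recovery target.

Autozygosity is planted afterwards as non-overlapping tracts of fixed
length inside chosen individuals: within a tract every genotype is made
homozygous by sampling one allele from the population frequency and
doubling it, so planted ROH keep a realistic allelic composition.  The
generator records tract coordinates and the implied true F_ROH per
individual.  Genotyping noise is sporadic missingness plus heterozygote
errors (a truly homozygous call flipped to heterozygous).

Defaults emulate a four-breed goat SNP-array study: sample sizes
(210, 82, 21, 24), ~46k autosomal SNPs over 29 autosomes spanning 2.46 Gb,
array-typical missingness and error rates (0.5% each), and a mid-range
drift of 0.075 (observed pairwise differentiation in such breed panels
spans roughly 0.015-0.14).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    INDIVIDUAL_COLUMNS,
    MARKER_COLUMNS,
    MISSING,
    GenotypeDataset,
)


@dataclass
class SimConfig:
    n_pops: int = 4
    n_per_pop: tuple[int, ...] = (210, 82, 21, 24)
    n_snps: int = 46_268
    n_chromosomes: int = 29
    genome_length_bp: int = 2_460_000_000
    divergence: float | tuple[float, ...] = 0.075
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.005
    het_error_rate: float = 0.005
    seed: int | None = None

    def drift(self) -> np.ndarray:
        f = np.broadcast_to(
            np.asarray(self.divergence, dtype=float), (self.n_pops,)
        ).copy()
        if ((f < 0) | (f >= 1)).any():
            raise ValueError("divergence F must be in [0, 1)")
        return f

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory (no silent nondeterminism)")
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("missing_rate", "het_error_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        self.drift()


@dataclass
class SimTruth:
    """Generator ground truth."""

    drift: np.ndarray
    chrom_lengths: dict[str, int]
    genome_length_bp: int
    pop_freqs: np.ndarray  # (n_pops, n_snps)
    planted_tracts: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (individual_id, chromosome, start_bp, end_bp)
    true_froh: dict[str, float] = field(default_factory=dict)

    def recompute_froh(self, individual_id: str) -> float:
        total = sum(
            end - start
            for iid, _c, start, end in self.planted_tracts
            if iid == individual_id
        )
        return total / self.genome_length_bp


def _chromosome_lengths(cfg: SimConfig) -> np.ndarray:
    """Linearly decreasing chromosome sizes scaled to the genome length."""
    raw = np.linspace(150.0, 40.0, cfg.n_chromosomes)
    return np.round(raw / raw.sum() * cfg.genome_length_bp).astype(np.int64)


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, int]]:
    lengths = _chromosome_lengths(cfg)
    counts = np.floor(lengths / lengths.sum() * cfg.n_snps).astype(int)
    counts[: cfg.n_snps - counts.sum()] += 1  # distribute the remainder
    rows = []
    chrom_lengths = {}
    for c in range(cfg.n_chromosomes):
        label = str(c + 1)
        chrom_lengths[label] = int(lengths[c])
        k = int(counts[c])
        pos = np.sort(
            rng.choice(np.int64(lengths[c]), size=k, replace=False) + 1
        )
        for j, p in enumerate(pos):
            rows.append((f"snp_{label}_{j + 1}", label, int(p), "A", "G"))
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return markers, chrom_lengths


def simulate_populations(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Draw a multi-population dataset under the Balding-Nichols model."""
    rng = np.random.default_rng(cfg.seed)
    markers, chrom_lengths = _marker_map(cfg, rng)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)
    drift = cfg.drift()

    pop_freqs = np.empty((cfg.n_pops, cfg.n_snps))
    for i, f in enumerate(drift):
        if f == 0.0:
            pop_freqs[i] = p_anc
        else:
            scale = (1.0 - f) / f
            pop_freqs[i] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    ind_rows = []
    call_blocks = []
    for i in range(cfg.n_pops):
        pop = f"pop{i + 1}"
        n = cfg.n_per_pop[i]
        ind_rows.extend((f"{pop}_ind{j + 1}", pop) for j in range(n))
        call_blocks.append(
            rng.binomial(2, pop_freqs[i][None, :], size=(n, cfg.n_snps)).astype(
                np.int8
            )
        )
    individuals = pd.DataFrame(ind_rows, columns=INDIVIDUAL_COLUMNS)
    calls = np.vstack(call_blocks)
    ds = GenotypeDataset(markers=markers, individuals=individuals, calls=calls)
    truth = SimTruth(
        drift=drift,
        chrom_lengths=chrom_lengths,
        genome_length_bp=cfg.genome_length_bp,
        pop_freqs=pop_freqs,
        true_froh={iid: 0.0 for iid, _ in ind_rows},
    )
    return ds, truth


def plant_autozygosity(
    ds: GenotypeDataset,
    truth: SimTruth,
    individual_id: str,
    target_froh: float,
    tract_length_bp: int,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> None:
    """Plant non-overlapping homozygous tracts until the target F_ROH is met.

    Tracts of ``tract_length_bp`` are placed on random autosomes (chosen
    proportionally to length) until the summed tract length reaches
    ``target_froh * genome_length_bp``; the achieved total therefore
    overshoots the target by less than one tract.  Modifies ``ds`` and
    ``truth`` in place.
    """
    if not (0.0 <= target_froh <= 1.0):
        raise ValueError("target_froh must be in [0, 1]")
    i = ds.individual_index(individual_id)
    pop = ds.individuals["population"].iat[i]
    pop_order = list(dict.fromkeys(ds.individuals["population"]))
    pop_idx = pop_order.index(pop)

    chroms = list(truth.chrom_lengths)
    lengths = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    existing: dict[str, list[tuple[int, int]]] = {}
    for iid, c, s, e in truth.planted_tracts:
        if iid == individual_id:
            existing.setdefault(c, []).append((s, e))

    chrom_col = ds.markers["chromosome"].astype(str).to_numpy()
    pos_col = ds.markers["position_bp"].to_numpy()

    total = sum(e - s for v in existing.values() for (s, e) in v)
    goal = target_froh * truth.genome_length_bp
    tries = 0
    while total < goal:
        if tries >= max_tries:
            raise RuntimeError(
                "could not place non-overlapping tracts; achieved F_ROH "
                f"{total / truth.genome_length_bp:.4f} of target {target_froh}"
            )
        tries += 1
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        clen = truth.chrom_lengths[c]
        if clen <= tract_length_bp:
            continue
        start = int(rng.integers(1, clen - tract_length_bp + 1))
        end = start + tract_length_bp
        if any(s < end and start < e for (s, e) in existing.get(c, [])):
            continue
        existing.setdefault(c, []).append((start, end))
        truth.planted_tracts.append((individual_id, c, start, end))
        total += tract_length_bp

        in_tract = (
            (chrom_col == c) & (pos_col >= start) & (pos_col <= end)
        )
        j = np.flatnonzero(in_tract)
        allele = rng.random(j.size) < truth.pop_freqs[pop_idx, j]
        ds.calls[i, j] = (2 * allele).astype(np.int8)

    truth.true_froh[individual_id] = total / truth.genome_length_bp


def inject_noise(
    ds: GenotypeDataset,
    missing_rate: float,
    het_error_rate: float,
    rng: np.random.Generator,
) -> GenotypeDataset:
    """Apply sporadic missingness, then heterozygote errors, in place.

    Each call independently becomes :data:`MISSING` with ``missing_rate``;
    each surviving homozygous call flips to heterozygous with
    ``het_error_rate``.
    """
    for name, r in (("missing_rate", missing_rate), ("het_error_rate", het_error_rate)):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if missing_rate > 0:
        drop = rng.random(ds.calls.shape) < missing_rate
        ds.calls[drop] = MISSING
    if het_error_rate > 0:
        hom = (ds.calls == 0) | (ds.calls == 2)
        flip = hom & (rng.random(ds.calls.shape) < het_error_rate)
        ds.calls[flip] = 1
    return ds
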