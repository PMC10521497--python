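"""SNP-array quality control.

The filter set is deliberately minimal: positional filters (autosomes 1-29
only, known unique positions) plus call-rate thresholds for individuals and
markers.  No Hardy-Weinberg, LD-pruning or MAF filter is applied anywhere in
the pipeline: inbreeding itself causes HWE departures, LD carries the very
selection signal ROH analysis looks for, and MAF filtering discards
homozygous regions.

Filter order (fixed so removal counts are reproducible):

1. positional: unknown position (chromosome '0'/blank or bp 0), sex/other
   non-autosomal chromosomes, and every member of a duplicated
   (chromosome, position) set;
2. individuals with call rate below ``indiv_cr`` over the remaining markers;
3. markers with call rate below ``marker_cr`` over the remaining individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AUTOSOMES, MISSING, GenotypeDataset


@dataclass
class QCReport:
    """Bookkeeping of one :func:`filter_dataset` run."""

    n_markers_in: int
    n_markers_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed_markers: list[tuple[str, str]] = field(default_factory=list)
    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    marker_call_rate: float = 0.99
    individual_call_rate: float = 0.90
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_markers_in - len(self.removed_markers) != self.n_markers_out:
            raise AssertionError("marker bookkeeping does not reconcile")
        if (
            self.n_individuals_in - len(self.removed_individuals)
            != self.n_individuals_out
        ):
            raise AssertionError("individual bookkeeping does not reconcile")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        mk = pd.DataFrame(self.removed_markers, columns=["snp_id", "reason"])
        ind = pd.DataFrame(
            self.removed_individuals, columns=["individual_id", "reason"]
        )
        return mk, ind

    def summary(self) -> str:
        lines = [
            f"markers: {self.n_markers_in} in, "
            f"{len(self.removed_markers)} removed, {self.n_markers_out} kept",
            f"individuals: {self.n_individuals_in} in, "
            f"{len(self.removed_individuals)} removed, "
            f"{self.n_individuals_out} kept",
            f"thresholds: marker call rate >= {self.marker_call_rate}, "
            f"individual call rate >= {self.individual_call_rate}",
        ]
        lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def call_rate(calls: np.ndarray) -> float:
    """Fraction of non-missing calls in a genotype vector."""
    v = np.asarray(calls)
    if v.size == 0:
        raise ValueError("call rate of an empty vector is undefined")
    return float(np.count_nonzero(v != MISSING) / v.size)


def filter_dataset(
    ds: GenotypeDataset,
    marker_cr: float = 0.99,
    indiv_cr: float = 0.90,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply positional and call-rate filters; report every removal.

    Each removed marker/individual carries exactly one reason: the first
    rule that fired.  An empty dataset after filtering is a warning in the
    report, not an error.
    """
    for name, thr in (("marker_cr", marker_cr), ("indiv_cr", indiv_cr)):
        if not (0.0 < thr <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {thr}")

    report = QCReport(
        n_markers_in=ds.n_markers,
        n_markers_out=0,
        n_individuals_in=ds.n_individuals,
        n_individuals_out=0,
        marker_call_rate=marker_cr,
        individual_call_rate=indiv_cr,
    )

    markers = ds.markers
    chrom = markers["chromosome"].astype(str).to_numpy()
    pos = markers["position_bp"].to_numpy()
    snp_ids = markers["snp_id"].to_numpy()

    # 1. positional filters
    unknown = (pos <= 0) | (chrom == "0") | (chrom == "")
    non_auto = ~np.isin(chrom, sorted(AUTOSOMES)) & ~unknown
    key = pd.Series(list(zip(chrom, pos)))
    dup = key.duplicated(keep=False).to_numpy() & ~unknown & ~non_auto

    marker_keep = ~(unknown | non_auto | dup)
    for j in np.flatnonzero(unknown):
        report.removed_markers.append((snp_ids[j], "unknown_position"))
    for j in np.flatnonzero(non_auto):
        report.removed_markers.append((snp_ids[j], "non_autosomal"))
    for j in np.flatnonzero(dup):
        report.removed_markers.append((snp_ids[j], "duplicate_position"))

    calls = ds.calls[:, marker_keep]

    # 2. individual call rate over remaining markers
    if calls.shape[1] > 0:
        ind_cr = (calls != MISSING).mean(axis=1)
    else:
        ind_cr = np.ones(ds.n_individuals)
    ind_keep = ind_cr >= indiv_cr
    for i in np.flatnonzero(~ind_keep):
        report.removed_individuals.append(
            (ds.individuals["individual_id"].iat[i], "call_rate")
        )

    calls = calls[ind_keep, :]

    # 3. marker call rate over remaining individuals
    kept_marker_idx = np.flatnonzero(marker_keep)
    if calls.shape[0] > 0:
        mk_cr = (calls != MISSING).mean(axis=0)
    else:
        mk_cr = np.ones(kept_marker_idx.size)
    low = mk_cr < marker_cr
    for j in kept_marker_idx[low]:
        report.removed_markers.append((snp_ids[j], "call_rate"))
    kept_marker_idx = kept_marker_idx[~low]

    out = ds.subset(
        individual_idx=np.flatnonzero(ind_keep), marker_idx=kept_marker_idx
    ).sorted_by_map()

    report.n_markers_out = out.n_markers
    report.n_individuals_out = out.n_individuals
    if out.n_markers == 0 or out.n_individuals == 0:
        report.warnings.append("dataset is empty after filtering")
    report.validate()
    return out, report
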