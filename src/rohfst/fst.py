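"""Per-SNP Weir-Cockerham F_ST for pairs of populations.

The two-population variance-components estimator theta-hat = a / (a+b+c)
is computed per SNP from sample sizes ``n_i``, allele-B frequencies ``p_i``
and observed heterozygote frequencies ``h_i`` (missing genotypes excluded
per SNP).  With r = 2 samples and

    n_bar = (n1 + n2) / 2
    n_c   = 2 n_bar - (n1^2 + n2^2) / (2 n_bar)
    p_bar = (n1 p1 + n2 p2) / (2 n_bar)
    s2    = [n1 (p1 - p_bar)^2 + n2 (p2 - p_bar)^2] / n_bar
    h_bar = (n1 h1 + n2 h2) / (2 n_bar)

the components are

    a = (n_bar / n_c) * [s2 - (p_bar (1 - p_bar) - s2/2 - h_bar/4) / (n_bar - 1)]
    b = (n_bar / (n_bar - 1)) * [p_bar (1 - p_bar) - s2/2 - (2 n_bar - 1) / (4 n_bar) * h_bar]
    c = h_bar / 2

theta is undefined when a + b + c = 0 (monomorphic across both samples with
no heterozygotes) or when n_bar = 1.  Negative per-SNP estimates are kept:
clamping them would bias averages upward.  The pairwise mean is the
unweighted arithmetic mean of defined per-SNP theta; a ratio-of-sums
variant sum(a)/sum(a+b+c) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset


@dataclass
class FstRecord:
    """Weir-Cockerham components for one SNP and one population pair."""

    snp_id: str
    chromosome: str
    position_bp: int
    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float
    a: float
    b: float
    c: float
    theta: float  # NaN when undefined


@dataclass
class PairwiseFst:
    pop_a: str
    pop_b: str
    mean_theta: float
    weighted_theta: float
    n_snps_used: int
    records: pd.DataFrame  # one row per retained marker


def _wc_components(
    n1: np.ndarray,
    n2: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    h1: np.ndarray,
    h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised a, b, c, theta; NaN where the estimator is undefined."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / 2.0
        valid = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
        nbar_s = np.where(valid, nbar, 2.0)  # safe denominator
        nc = 2.0 * nbar_s - (n1**2 + n2**2) / (2.0 * nbar_s)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar_s)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar_s
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar_s)
        inner = pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar_s / nc) * (s2 - inner / (nbar_s - 1.0))
        b = (nbar_s / (nbar_s - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 / 2.0
            - (2.0 * nbar_s - 1.0) / (4.0 * nbar_s) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    theta = np.where(valid, theta, np.nan)
    return a, b, c, theta


def wc_fst_snp(
    counts1: tuple[int, int, int], counts2: tuple[int, int, int]
) -> FstRecord:
    """Estimator for a single SNP from genotype counts (AA, AB, BB).

    ``AA`` is the allele-A homozygote, ``AB`` the heterozygote, ``BB`` the
    allele-B homozygote; allele-B frequency is the ``p`` of the formulas.
    """
    (aa1, ab1, bb1) = counts1
    (aa2, ab2, bb2) = counts2
    n1 = aa1 + ab1 + bb1
    n2 = aa2 + ab2 + bb2
    if n1 >= 1 and n2 >= 1:
        p1 = (ab1 + 2 * bb1) / (2 * n1)
        p2 = (ab2 + 2 * bb2) / (2 * n2)
        h1 = ab1 / n1
        h2 = ab2 / n2
    else:
        p1 = p2 = h1 = h2 = np.nan
    a, b, c, theta = _wc_components(
        np.array([n1]), np.array([n2]),
        np.array([p1]), np.array([p2]),
        np.array([h1]), np.array([h2]),
    )
    return FstRecord(
        snp_id="",
        chromosome="",
        position_bp=0,
        n1=n1,
        n2=n2,
        p1=float(p1),
        p2=float(p2),
        h1=float(h1),
        h2=float(h2),
        a=float(a[0]),
        b=float(b[0]),
        c=float(c[0]),
        theta=float(theta[0]),
    )


def _pop_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP genotyped count, allele-B frequency, heterozygote frequency."""
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(float)
    dose = np.where(nonmiss, calls, 0).sum(axis=0)
    het = ((calls == 1) & nonmiss).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, dose / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def pairwise_fst(
    ds: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    clamp_negative: bool = False,
) -> PairwiseFst:
    """Weir-Cockerham theta at every marker plus pairwise means.

    ``mean_theta`` averages defined per-SNP theta (negatives retained unless
    ``clamp_negative``); ``weighted_theta`` is sum(a)/sum(a+b+c) over defined
    SNPs.  No MAF filter is applied.
    """
    pops = set(ds.individuals["population"])
    for p in (pop_a, pop_b):
        if p not in pops:
            raise ValueError(f"unknown population label {p!r}")
    mask_a = (ds.individuals["population"] == pop_a).to_numpy()
    mask_b = (ds.individuals["population"] == pop_b).to_numpy()

    n1, p1, h1 = _pop_stats(ds.calls[mask_a])
    n2, p2, h2 = _pop_stats(ds.calls[mask_b])
    a, b, c, theta = _wc_components(n1, n2, p1, p2, h1, h2)
    if clamp_negative:
        theta = np.where(np.isnan(theta), np.nan, np.clip(theta, 0.0, None))

    records = pd.DataFrame(
        {
            "snp_id": ds.markers["snp_id"],
            "chr": ds.markers["chromosome"].astype(str),
            "position_bp": ds.markers["position_bp"],
            "n1": n1.astype(int),
            "n2": n2.astype(int),
            "p1": p1,
            "p2": p2,
            "h1": h1,
            "h2": h2,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )
    defined = ~np.isnan(theta)
    n_used = int(defined.sum())
    mean_theta = float(np.nanmean(theta)) if n_used else float("nan")
    denom = np.nansum((a + b + c)[defined])
    weighted = float(np.nansum(a[defined]) / denom) if denom != 0 else float("nan")
    return PairwiseFst(
        pop_a=pop_a,
        pop_b=pop_b,
        mean_theta=mean_theta,
        weighted_theta=weighted,
        n_snps_used=n_used,
        records=records,
    )


def fst_matrix(
    ds: GenotypeDataset, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pairwise mean-theta matrix over population pairs (Table-3 shape)."""
    pops = ds.populations()
    if pairs is None:
        pairs = [
            (pops[i], pops[j])
            for i in range(len(pops))
            for j in range(i + 1, len(pops))
        ]
    mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    for a, b in pairs:
        pf = pairwise_fst(ds, a, b)
        mat.loc[a, b] = pf.mean_theta
        mat.loc[b, a] = pf.mean_theta
    return mat


def top_snps(
    pf: PairwiseFst,
    ds: GenotypeDataset,
    k: int = 10,
    flank_bp: int = 500_000,
) -> pd.DataFrame:
    """The k highest-theta SNPs with +/- flank candidate windows.

    Ties are broken by map order.  Windows are clipped at position 1 and at
    the last SNP position of the chromosome.  If fewer than k SNPs have a
    defined theta, all of them are returned.
    """
    rec = pf.records
    defined = rec.dropna(subset=["theta"])
    if len(defined) < k:
        k = len(defined)
    # stable sort keeps map order among ties
    top = defined.sort_values("theta", ascending=False, kind="stable").head(k)
    chrom_last = (
        ds.markers.groupby(ds.markers["chromosome"].astype(str))["position_bp"]
        .max()
        .to_dict()
    )
    rows = []
    for r in top.itertuples(index=False):
        last = int(chrom_last[str(r.chr)])
        start = max(1, int(r.position_bp) - flank_bp)
        end = min(last, int(r.position_bp) + flank_bp)
        rows.append(
            {
                "snp_id": r.snp_id,
                "chr": r.chr,
                "position_bp": int(r.position_bp),
                "theta": r.theta,
                "window_start_bp": start,
                "window_end_bp": end,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "chr",
            "position_bp",
            "theta",
            "window_start_bp",
            "window_end_bp",
        ],
    )
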