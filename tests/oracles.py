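"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations of the statistics under test
(per-interval rescans, scalar formula transcriptions, per-marker membership
scans); they share no code with the package implementations.
"""

from __future__ import annotations

import math

MISSING = -1


def roh_oracle(g, pos, *, min_snps, min_length_bp, max_gap_bp, max_het, max_missing):
    """Exhaustive-enumeration ROH caller for one individual/chromosome.

    Left to right: take the qualifying interval with the leftmost feasible
    start and maximal end, then continue after it.  A qualifying interval
    starts and ends on a homozygous non-missing call, keeps every
    inter-SNP gap <= max_gap_bp, contains at most max_het heterozygous and
    max_missing missing calls, and meets the SNP-count and bp-length
    minima.  Each candidate interval is re-counted from scratch.
    """
    n = len(g)
    is_hom = [x in (0, 2) for x in g]
    out = []
    cursor = 0
    while cursor < n:
        found = None
        for s in range(cursor, n):
            if not is_hom[s]:
                continue
            best = -1
            for e in range(s, n):
                if e > s and pos[e] - pos[e - 1] > max_gap_bp:
                    break
                window = list(g[s : e + 1])
                if window.count(1) > max_het:
                    break
                if window.count(MISSING) > max_missing:
                    break
                if (
                    is_hom[e]
                    and e - s + 1 >= min_snps
                    and pos[e] - pos[s] >= min_length_bp
                ):
                    best = e
            if best >= 0:
                found = (s, best)
                break
        if found is None:
            break
        out.append(found)
        cursor = found[1] + 1
    return out


def wc_theta_oracle(counts1, counts2):
    """Scalar two-population Weir-Cockerham components from genotype counts.

    counts are (AA, AB, BB) with B the dosage-counted allele.  Returns
    (a, b, c, theta); any value is NaN when undefined.
    """
    aa1, ab1, bb1 = counts1
    aa2, ab2, bb2 = counts2
    n1 = aa1 + ab1 + bb1
    n2 = aa2 + ab2 + bb2
    nan = float("nan")
    if n1 < 1 or n2 < 1:
        return nan, nan, nan, nan
    nbar = (n1 + n2) / 2
    if nbar <= 1:
        return nan, nan, nan, nan
    p1 = (ab1 + 2 * bb1) / (2 * n1)
    p2 = (ab2 + 2 * bb2) / (2 * n2)
    h1 = ab1 / n1
    h2 = ab2 / n2
    nc = 2 * nbar - (n1 * n1 + n2 * n2) / (2 * nbar)
    pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else nan
    return a, b, c, theta


def incidence_oracle(segments, markers, individual_ids):
    """Per-marker covered fraction by direct membership scan.

    ``segments``: iterable of (individual_id, chromosome, start_bp, end_bp);
    ``markers``: list of (chromosome, position_bp) tuples.
    """
    fractions = []
    ids = list(individual_ids)
    for chrom, bp in markers:
        covered = 0
        for iid in ids:
            if any(
                sid == iid and c == chrom and s <= bp <= e
                for (sid, c, s, e) in segments
            ):
                covered += 1
        fractions.append(covered / len(ids))
    return fractions


def expected_qc_removals(calls, marker_cr, indiv_cr):
    """Brute-force call-rate removal sets (no positional issues assumed).

    Returns (removed_individual_indices, removed_marker_indices) applying
    individuals-then-markers, counting missing as MISSING entries.
    """
    n_ind = len(calls)
    n_mk = len(calls[0]) if n_ind else 0
    removed_ind = []
    for i in range(n_ind):
        ok = sum(1 for j in range(n_mk) if calls[i][j] != MISSING)
        if ok / n_mk < indiv_cr:
            removed_ind.append(i)
    kept_ind = [i for i in range(n_ind) if i not in removed_ind]
    removed_mk = []
    for j in range(n_mk):
        if not kept_ind:
            break
        ok = sum(1 for i in kept_ind if calls[i][j] != MISSING)
        if ok / len(kept_ind) < marker_cr:
            removed_mk.append(j)
    return removed_ind, removed_mk


def froh_oracle(segment_lengths_bp, l_auto_bp):
    return math.fsum(segment_lengths_bp) / l_auto_bp
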