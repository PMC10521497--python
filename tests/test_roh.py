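"""Consecutive-runs ROH detection, length classes, summaries and F_ROH."""

import numpy as np
import pytest

from conftest import make_dataset
from oracles import roh_oracle
from rohfst.io import MISSING, ROHSegment
from rohfst.roh import (
    GOAT_L_AUTO_BP,
    ROHParams,
    breed_summary_frame,
    chromosome_spans,
    classify_lengths,
    compute_froh,
    detect_roh,
    froh_table,
    summarize_by_breed,
)

DEFAULT = ROHParams()


def seg(length_bp, chrom="1", iid="ind1", pop="popA", start=1_000_000, n_snps=30):
    return ROHSegment(
        individual_id=iid,
        population=pop,
        chromosome=chrom,
        start_bp=start,
        end_bp=start + length_bp,
        n_snps=n_snps,
    )


class TestDetect:
    def test_all_heterozygous_yields_nothing(self):
        ds = make_dataset(np.ones((1, 40), dtype=np.int8))
        assert detect_roh(ds, DEFAULT) == []

    def test_qualifying_run_flanked_by_hets(self):
        # 25 homozygous SNPs spanning exactly 500 kb, >=2 hets on each side
        hom_pos = np.linspace(100_000, 600_000, 25).astype(int).tolist()
        positions = [1_000, 2_000] + hom_pos + [610_000, 620_000]
        calls = np.array([[1, 1] + [0] * 25 + [1, 1]], dtype=np.int8)
        ds = make_dataset(calls, positions=positions)
        out = detect_roh(ds, DEFAULT)
        assert len(out) == 1
        s = out[0]
        assert s.n_snps == 25
        assert (s.start_bp, s.end_bp) == (100_000, 600_000)
        assert s.length_bp == 500_000

    def test_short_span_fails_min_length(self):
        # 25 homozygous SNPs spanning only 200 kb
        positions = np.linspace(100_000, 300_000, 25).astype(int).tolist()
        ds = make_dataset(np.zeros((1, 25), dtype=np.int8), positions=positions)
        assert detect_roh(ds, DEFAULT) == []

    def test_few_snps_fails_min_count(self):
        positions = np.linspace(100_000, 600_000, 19).astype(int).tolist()
        ds = make_dataset(np.zeros((1, 19), dtype=np.int8), positions=positions)
        assert detect_roh(ds, DEFAULT) == []

    def test_large_gap_splits_run(self):
        # 40 homozygous SNPs with a 2 Mb gap in the middle: two runs
        left = np.linspace(100_000, 600_000, 20).astype(int)
        right = np.linspace(2_700_000, 3_200_000, 20).astype(int)
        positions = np.concatenate([left, right]).tolist()
        ds = make_dataset(np.zeros((1, 40), dtype=np.int8), positions=positions)
        out = detect_roh(ds, DEFAULT)
        assert [(s.start_bp, s.end_bp) for s in out] == [
            (100_000, 600_000),
            (2_700_000, 3_200_000),
        ]

    def test_quota_heterozygote_inside_run_allowed(self):
        positions = np.linspace(100_000, 600_000, 25).astype(int).tolist()
        calls = np.zeros((1, 25), dtype=np.int8)
        calls[0, 12] = 1  # one het within quota
        ds = make_dataset(calls, positions=positions)
        out = detect_roh(ds, DEFAULT)
        assert len(out) == 1 and out[0].n_snps == 25
        calls[0, 13] = 1  # second het breaks the 25-SNP run
        ds2 = make_dataset(calls, positions=positions)
        assert detect_roh(ds2, DEFAULT) == []

    def test_unsorted_markers_rejected(self):
        ds = make_dataset(
            np.zeros((1, 3), dtype=np.int8), positions=[3_000, 1_000, 2_000]
        )
        with pytest.raises(ValueError, match="not position-sorted"):
            detect_roh(ds, DEFAULT)

    @pytest.mark.parametrize("bad", [{"min_snps": 0}, {"max_gap_bp": -1}])
    def test_param_validation(self, bad):
        with pytest.raises(ValueError):
            ROHParams(**bad)


def _random_chromosome(rng, n_max=60):
    n = int(rng.integers(1, n_max))
    g = rng.choice(
        [0, 1, 2, MISSING], size=n, p=[0.35, 0.25, 0.3, 0.1]
    ).astype(np.int8)
    pos = np.sort(
        rng.choice(np.arange(1, 3_000_000), size=n, replace=False)
    ).astype(np.int64)
    return g, pos


class TestOracleEquivalence:
    """The linear-scan detector must equal exhaustive interval enumeration."""

    def test_random_instances(self):
        rng = np.random.default_rng(42)
        params = ROHParams(
            min_snps=5,
            min_length_bp=50_000,
            max_gap_bp=200_000,
            max_het=1,
            max_missing=1,
        )
        for _ in range(200):
            g, pos = _random_chromosome(rng)
            ds = make_dataset(g[None, :], positions=pos.tolist())
            got = [
                (s.start_bp, s.end_bp, s.n_snps) for s in detect_roh(ds, params)
            ]
            exp = [
                (int(pos[s]), int(pos[e]), e - s + 1)
                for s, e in roh_oracle(
                    g.tolist(),
                    pos.tolist(),
                    min_snps=params.min_snps,
                    min_length_bp=params.min_length_bp,
                    max_gap_bp=params.max_gap_bp,
                    max_het=params.max_het,
                    max_missing=params.max_missing,
                )
            ]
            assert got == exp

    def test_segments_never_overlap(self):
        rng = np.random.default_rng(7)
        params = ROHParams(min_snps=3, min_length_bp=10_000, max_gap_bp=500_000)
        for _ in range(100):
            g, pos = _random_chromosome(rng)
            ds = make_dataset(g[None, :], positions=pos.tolist())
            out = detect_roh(ds, params)
            spans = sorted((s.start_bp, s.end_bp) for s in out)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_endpoints_are_homozygous_members(self):
        rng = np.random.default_rng(8)
        params = ROHParams(min_snps=3, min_length_bp=10_000, max_gap_bp=500_000)
        for _ in range(100):
            g, pos = _random_chromosome(rng)
            ds = make_dataset(g[None, :], positions=pos.tolist())
            for s in detect_roh(ds, params):
                i = int(np.searchsorted(pos, s.start_bp))
                j = int(np.searchsorted(pos, s.end_bp))
                assert pos[i] == s.start_bp and pos[j] == s.end_bp
                assert g[i] in (0, 2) and g[j] in (0, 2)


class TestLengthClasses:
    def test_boundary_is_half_open(self):
        counts = classify_lengths([seg(2_000_000)])
        assert counts["2-4 Mb"] == 1 and counts["0-2 Mb"] == 0

    def test_above_sixteen(self):
        assert classify_lengths([seg(17_000_000)])[">16 Mb"] == 1

    def test_planted_lengths_partition(self):
        segs = [seg(1_000_000), seg(3_000_000), seg(9_000_000)]
        counts = classify_lengths(segs)
        assert [counts[k] for k in ["0-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", ">16 Mb"]] == [
            1, 1, 0, 1, 0,
        ]
        assert sum(counts.values()) == len(segs)


class TestSummaries:
    def test_counts_and_mean_lengths(self):
        ds = make_dataset(np.zeros((1, 3), dtype=np.int8))
        segs = [seg(1_000_000, start=1), seg(1_000_000, start=5_000_000)]
        (summary,) = summarize_by_breed(segs, ds)
        assert summary.total_roh == 2
        assert summary.mean_count == 2
        assert summary.mean_total_length_mb == pytest.approx(2.0)

    def test_population_without_segments_is_all_zero(self):
        ds = make_dataset(
            np.zeros((2, 3), dtype=np.int8), populations=["popA", "popB"]
        )
        segs = [seg(1_000_000)]
        by_pop = {s.population: s for s in summarize_by_breed(segs, ds)}
        assert by_pop["popB"].total_roh == 0
        assert by_pop["popB"].mean_total_length_mb == 0.0

    def test_zero_segment_individuals_dilute_the_mean(self):
        ds = make_dataset(
            np.zeros((2, 3), dtype=np.int8), populations=["popA", "popA"]
        )
        (summary,) = summarize_by_breed([seg(2_000_000)], ds)
        assert summary.mean_count == pytest.approx(0.5)
        assert summary.mean_total_length_mb == pytest.approx(1.0)
        assert summary.n_individuals == 2

    def test_frame_shape(self):
        ds = make_dataset(np.zeros((1, 3), dtype=np.int8))
        df = breed_summary_frame(summarize_by_breed([seg(1_000_000)], ds))
        assert {"population", "total_roh", "mean_total_length_mb"} <= set(df.columns)


class TestFroh:
    def test_published_breed_means_reproduce(self):
        # mean accumulative ROH length 306.0 Mb -> F_ROH 0.12; 261.7 Mb -> 0.11
        for mb, expected in [(306.0, 0.12), (261.7, 0.11)]:
            res = compute_froh([seg(int(mb * 1e6))], GOAT_L_AUTO_BP)
            assert round(res.froh_genome, 2) == expected

    def test_no_segments_gives_zero(self):
        res = compute_froh([], GOAT_L_AUTO_BP, {"1": 1_000_000}, individual_id="x")
        assert res.froh_genome == 0.0
        assert all(v == 0.0 for v in res.froh_per_chromosome.values())

    def test_per_chromosome_denominator_is_snp_span(self):
        ds = make_dataset(
            np.zeros((1, 4), dtype=np.int8),
            chromosomes=["1", "1", "2", "2"],
            positions=[1_000_000, 11_000_000, 500_000, 4_500_000],
        )
        spans = chromosome_spans(ds)
        assert spans == {"1": 10_000_000, "2": 4_000_000}
        res = compute_froh(
            [seg(5_000_000, chrom="1", start=2_000_000)], GOAT_L_AUTO_BP, spans
        )
        assert res.froh_per_chromosome["1"] == pytest.approx(0.5)
        assert res.froh_per_chromosome["2"] == 0.0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="no span"):
            compute_froh([seg(1_000_000, chrom="9")], GOAT_L_AUTO_BP, {"1": 10})

    def test_mixed_individuals_rejected(self):
        with pytest.raises(ValueError, match="several individuals"):
            compute_froh([seg(1_000_000), seg(1_000_000, iid="ind2")])

    def test_froh_bounded(self, rng):
        lengths = rng.integers(250_000, 20_000_000, size=20)
        segs = [
            seg(int(l), start=int(1 + 30_000_000 * i))
            for i, l in enumerate(lengths)
        ]
        res = compute_froh(segs, GOAT_L_AUTO_BP)
        assert 0.0 <= res.froh_genome <= 1.0
        assert res.l_roh_bp == sum(int(l) for l in lengths)

    def test_froh_table_covers_all_individuals(self):
        ds = make_dataset(
            np.zeros((3, 3), dtype=np.int8),
            populations=["popA", "popA", "popB"],
        )
        df = froh_table([seg(2_460_000, iid="ind2")], ds)
        assert len(df) == 3
        by_id = df.set_index("individual_id")["froh_genome"]
        assert by_id["ind2"] == pytest.approx(0.001)
        assert by_id["ind1"] == 0.0


class TestPlantedRecovery:
    def test_exact_boundaries_on_heterozygous_background(self):
        # all-het background; one planted homozygous block is recovered
        # exactly at its member SNPs
        n = 200
        positions = (np.arange(n) * 50_000 + 1).tolist()
        calls = np.ones((1, n), dtype=np.int8)
        calls[0, 60:100] = 2
        ds = make_dataset(calls, positions=positions)
        out = detect_roh(ds, DEFAULT)
        assert len(out) == 1
        assert out[0].start_bp == positions[60]
        assert out[0].end_bp == positions[99]
        assert out[0].n_snps == 40


class TestHypothesisProperties:
    """Derandomised property checks over generated chromosomes."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _instance(draw, st):
        n = draw(st.integers(min_value=2, max_value=50))
        g = draw(
            st.lists(
                st.sampled_from([0, 1, 2, MISSING]), min_size=n, max_size=n
            )
        )
        steps = draw(
            st.lists(
                st.integers(min_value=1_000, max_value=400_000),
                min_size=n,
                max_size=n,
            )
        )
        pos = np.cumsum(steps).astype(np.int64)
        return np.array(g, dtype=np.int8), pos

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_detector_equals_oracle(self, data):
        g, pos = self._instance(data.draw, self.st)
        params = ROHParams(min_snps=4, min_length_bp=80_000, max_gap_bp=300_000)
        ds = make_dataset(g[None, :], positions=pos.tolist())
        got = [(s.start_bp, s.end_bp, s.n_snps) for s in detect_roh(ds, params)]
        exp = [
            (int(pos[s]), int(pos[e]), e - s + 1)
            for s, e in roh_oracle(
                g.tolist(),
                pos.tolist(),
                min_snps=params.min_snps,
                min_length_bp=params.min_length_bp,
                max_gap_bp=params.max_gap_bp,
                max_het=params.max_het,
                max_missing=params.max_missing,
            )
        ]
        assert got == exp

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_runs_satisfy_all_criteria(self, data):
        g, pos = self._instance(data.draw, self.st)
        params = ROHParams(min_snps=3, min_length_bp=50_000, max_gap_bp=500_000)
        ds = make_dataset(g[None, :], positions=pos.tolist())
        for seg in detect_roh(ds, params):
            i = int(np.searchsorted(pos, seg.start_bp))
            j = int(np.searchsorted(pos, seg.end_bp))
            window = g[i : j + 1]
            assert seg.n_snps == j - i + 1 >= params.min_snps
            assert seg.length_bp >= params.min_length_bp
            assert (window == 1).sum() <= params.max_het
            assert (window == MISSING).sum() <= params.max_missing
            assert (np.diff(pos[i : j + 1]) <= params.max_gap_bp).all()
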