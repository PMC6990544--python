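import numpy as np
import pytest

import rohscan as rs
from rohscan.rohdetect import candidate_segments, finalize_segments, window_hit_rates

from _oracle import brute_detect
from conftest import (
    dataset_from_calls,
    make_map,
    random_instance,
    segments_as_tuples,
    uniform_map,
)

PERMISSIVE = dict(window_het=0, window_missing=1, window_threshold=0.05,
                  min_snp=3, min_kb=100.0, max_density=1e6, max_gap_kb=1e6,
                  max_het=0)


class TestWindowHitRates:
    def test_fully_homozygous_chromosome(self):
        p = rs.RohParams(window_snp=100, window_het=0, window_missing=1,
                         **{k: v for k, v in PERMISSIVE.items()
                            if k not in ("window_het", "window_missing")})
        calls = np.zeros(300, dtype=np.int8)
        rates = window_hit_rates(calls, p)
        assert np.all(rates == 1.0)

    def test_short_chromosome_has_zero_windows(self):
        p = rs.RohParams(window_snp=100, **{k: v for k, v in PERMISSIVE.items()})
        rates = window_hit_rates(np.zeros(50, dtype=np.int8), p)
        assert rates.shape == (50,)
        assert np.all(rates == 0.0)

    def test_interior_snp_five_of_hundred_windows(self):
        """An interior SNP contained in exactly 5 homozygous windows of
        100 has hit rate 0.05, which meets threshold 0.05."""
        p = rs.RohParams(window_snp=100, window_het=0, window_missing=0,
                         window_threshold=0.05, min_snp=1, min_kb=1.0,
                         max_density=1e6, max_gap_kb=1e6, max_het=0)
        n = 300
        calls = np.ones(n, dtype=np.int8)  # heterozygous background
        # homozygous stretch making window starts 100..104 homozygous
        calls[100:204] = 0
        rates = window_hit_rates(calls, p)
        # SNP 150 lies in windows starting 51..150 -> 100 windows, 5 homozygous
        assert rates[150] == pytest.approx(0.05)
        assert rates[150] >= p.window_threshold - 1e-9

    def test_edge_denominator_counts_windows_containing_snp(self):
        p = rs.RohParams(window_snp=10, **PERMISSIVE)
        calls = np.zeros(30, dtype=np.int8)
        calls[:5] = 1  # first windows not homozygous
        rates = window_hit_rates(calls, p)
        # SNP 0 is in exactly 1 window (start 0), which is heterozygous
        assert rates[0] == 0.0
        # SNP 29 is in windows 20..20 (n-w=20): 1 window, homozygous
        assert rates[29] == 1.0


class TestCandidateSegments:
    def test_no_snp_passes(self):
        p = rs.RohParams(window_snp=5, **PERMISSIVE)
        ranges = candidate_segments(np.zeros(20), np.zeros(20, dtype=np.int8), p)
        assert ranges == []

    def test_single_full_run(self):
        p = rs.RohParams(window_snp=5, **PERMISSIVE)
        ranges = candidate_segments(np.ones(120), np.zeros(120, dtype=np.int8), p)
        assert ranges == [(0, 119)]

    def test_heterozygous_ends_trimmed(self):
        p = rs.RohParams(window_snp=5, **PERMISSIVE)
        calls = np.zeros(10, dtype=np.int8)
        calls[0] = 1
        calls[9] = -1
        ranges = candidate_segments(np.ones(10), calls, p)
        assert ranges == [(1, 8)]


class TestFinalizeSegments:
    def test_gap_split(self):
        # 1500-kb internal gap with max_gap 1000 -> two pieces
        m = make_map({1: [1 + 50_000 * k for k in range(30)]
                      + [1 + 50_000 * 29 + 1_500_000 + 50_000 * k for k in range(1, 31)]})
        calls = np.zeros(60, dtype=np.int8)
        p = rs.RohParams(window_snp=5, window_het=0, window_missing=1,
                         window_threshold=0.05, min_snp=3, min_kb=100.0,
                         max_density=1e6, max_gap_kb=1000.0, max_het=0)
        segs = finalize_segments([(0, 59)], calls, m, p, "i", "1")
        assert len(segs) == 2
        assert segs[0].n_snp == 30 and segs[1].n_snp == 30

    def test_density_discard(self):
        # 10 SNPs spanning ~2000 kb -> 200 kb/SNP > 150 -> discarded
        m = make_map({1: [1 + int(k * 2_000_000 / 9) for k in range(10)]})
        calls = np.zeros(10, dtype=np.int8)
        p = rs.RohParams(window_snp=3, window_het=0, window_missing=1,
                         window_threshold=0.05, min_snp=1, min_kb=100.0,
                         max_density=150.0, max_gap_kb=1e6, max_het=0)
        assert finalize_segments([(0, 9)], calls, m, p, "i", "1") == []

    def test_min_kb_discard(self):
        m = make_map({1: [1 + 100_000 * k for k in range(10)]})  # span 900 kb
        calls = np.zeros(10, dtype=np.int8)
        p = rs.RohParams(window_snp=3, window_het=0, window_missing=1,
                         window_threshold=0.05, min_snp=1, min_kb=1000.0,
                         max_density=1e6, max_gap_kb=1e6, max_het=0)
        assert finalize_segments([(0, 9)], calls, m, p, "i", "1") == []

    def test_het_excised_and_pieces_kept(self):
        m = uniform_map(n_snp=21, spacing_kb=50)
        calls = np.zeros(21, dtype=np.int8)
        calls[10] = 1
        p = rs.RohParams(window_snp=3, window_het=1, window_missing=1,
                         window_threshold=0.05, min_snp=2, min_kb=100.0,
                         max_density=1e6, max_gap_kb=1e6, max_het=0)
        segs = finalize_segments([(0, 20)], calls, m, p, "i", "1")
        assert len(segs) == 2
        assert segs[0].n_snp == 10 and segs[1].n_snp == 10
        assert all(s.n_het == 0 for s in segs)


class TestDetectRoh:
    def test_fully_homozygous_individual_spans_each_chromosome(self):
        m = uniform_map(n_chrom=3, n_snp=80, spacing_kb=50)
        ds = rs.homozygous_individual(m)
        p = rs.RohParams(window_snp=20, **PERMISSIVE)
        segs = rs.detect_roh(ds, p)
        assert len(segs) == 3
        for c, seg in zip(m.chromosomes(), segs):
            pos = m.bp[m.chrom == c]
            assert (seg.start_bp, seg.end_bp) == (pos[0], pos[-1])
            assert seg.n_snp == 80

    def test_alternating_heterozygous_yields_nothing(self):
        m = uniform_map(n_snp=100, spacing_kb=50)
        calls = np.zeros(100, dtype=np.int8)
        calls[1::2] = 1
        ds = dataset_from_calls(m, calls)
        p = rs.RohParams(window_snp=10, **PERMISSIVE)
        assert rs.detect_roh(ds, p) == []

    def test_matches_brute_force_on_planted_segments(self):
        spec = rs.SynthSpec(
            n_chromosomes=1, snps_per_chromosome=200, n_individuals=2,
            spacing_kb=60, planted_segments={0: ((0, 20, 50), (0, 120, 40))},
            background_het=0.35, missing_rate=0.01, seed=77,
        )
        ds, _ = rs.generate(spec)
        p = rs.RohParams(window_snp=10, window_het=0, window_missing=1,
                         window_threshold=0.05, min_snp=10, min_kb=500.0,
                         max_density=200.0, max_gap_kb=2000.0, max_het=0)
        assert segments_as_tuples(rs.detect_roh(ds, p)) == brute_detect(ds, p)

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(25):
            ds, p = random_instance(rng)
            assert segments_as_tuples(rs.detect_roh(ds, p)) == brute_detect(ds, p)

    def test_segments_disjoint_and_satisfy_constraints(self, rng):
        for _ in range(10):
            ds, p = random_instance(rng, n_individuals=2)
            segs = rs.detect_roh(ds, p)
            by_key = {}
            for s in segs:
                assert s.length_kb >= p.min_kb
                assert s.n_snp >= p.min_snp
                assert s.length_kb / s.n_snp <= p.max_density
                assert s.n_het <= p.max_het
                assert s.length_kb == pytest.approx(
                    (s.end_bp - s.start_bp + 1) / 1000.0
                )
                by_key.setdefault((s.individual_id, s.chromosome), []).append(s)
            for group in by_key.values():
                group.sort(key=lambda s: s.start_bp)
                for a, b in zip(group, group[1:]):
                    assert a.end_bp < b.start_bp

    def test_stringency_monotonicity(self):
        spec = rs.SynthSpec(
            n_chromosomes=2, snps_per_chromosome=300, n_individuals=4,
            planted_segments={0: ((0, 30, 60),), 1: ((1, 100, 80),),
                              2: ((0, 150, 45),)},
            background_het=0.3, missing_rate=0.01, seed=13,
        )
        ds, _ = rs.generate(spec)

        def total(p):
            return sum(s.length_kb for s in rs.detect_roh(ds, p))

        base = rs.baseline_params(ds)
        for field, values, increasing_relaxes in [
            ("window_threshold", [0.05, 0.2, 0.5, 0.95], False),
            ("window_snp", [10, 20, 40, 80], False),
            ("max_gap_kb", [20.0, 100.0, 500.0, 2000.0], True),
            ("max_density", [10.0, 40.0, 80.0, 200.0], True),
        ]:
            totals = [
                total(rs.RohParams(**{**base.__dict__, field: v})) for v in values
            ]
            diffs = np.diff(totals)
            if increasing_relaxes:
                assert np.all(diffs >= -1e-9)
            else:
                assert np.all(diffs <= 1e-9)
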