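import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rohscan.io import MISSING
from rohscan.roh import (
    LengthClass,
    allowed_errors,
    calibrate_allowances,
    default_classes,
    detect_roh,
    scan_class,
    validate_classes,
)

from conftest import make_gm, make_map
from oracle import brute_force_scan, segments_as_tuples

CLS_12 = LengthClass("1-2", 1, 2, 0, 0)
CLS_OPEN = LengthClass("1+", 1, math.inf, 0, 0)


class TestScanClass:
    def test_all_het_sample_gives_nothing(self, uniform_map):
        assert scan_class(np.ones(100, dtype=np.int8), uniform_map, CLS_12) == []

    def test_forty_homozygous_markers_single_segment(self):
        # 40 markers spaced 50 kb span 1.95 Mb -> one run in class 1-2
        m = make_map({1: range(1, 40 * 50_000, 50_000)})
        segs = scan_class(np.zeros(40, dtype=np.int8), m, CLS_12)
        assert len(segs) == 1
        s = segs[0]
        assert (s.n_snps, s.length_bp, s.n_het, s.n_missing) == (40, 1_950_000, 0, 0)

    def test_split_at_heterozygote(self, uniform_map):
        # 100 hom markers, one het at index 50: two runs, each >=30 hom, >=1 Mb
        calls = np.zeros(100, dtype=np.int8)
        calls[50] = 1
        segs = scan_class(calls, uniform_map, LengthClass("1+", 1, math.inf, 0, 0))
        assert len(segs) == 2
        assert segs[0].n_snps == 50 and segs[1].n_snps == 49
        assert segments_as_tuples(segs) == brute_force_scan(calls, uniform_map, CLS_OPEN)

    def test_gap_rule_splits_runs(self):
        pos = list(range(1, 35 * 50_000, 50_000))
        pos += [pos[-1] + 1_000_001 + 50_000 * k for k in range(35)]
        m = make_map({1: pos})
        segs = scan_class(np.zeros(70, dtype=np.int8), m, CLS_OPEN)
        assert len(segs) == 2

    def test_trimming_to_homozygous_endpoints(self):
        # missing at both flanks of a 4-8 Mb run must be trimmed off
        m = make_map({1: range(1, 110 * 50_000, 50_000)})
        calls = np.zeros(110, dtype=np.int8)
        calls[0] = MISSING
        cls = LengthClass("4-8", 4, 8, 0, 1)
        segs = scan_class(calls, m, cls)
        assert len(segs) == 1
        assert segs[0].start_bp == 50_001 and segs[0].n_missing == 0

    def test_unaligned_calls_rejected(self, uniform_map):
        with pytest.raises(ValueError, match="aligned"):
            scan_class(np.zeros(5, dtype=np.int8), uniform_map, CLS_12)


def random_panel(rng, n_markers, n_chrom=2):
    chroms = {}
    left = n_markers
    for c in range(1, n_chrom + 1):
        k = left if c == n_chrom else rng.integers(1, left - (n_chrom - c) + 1)
        # gaps occasionally exceed 1 Mb to exercise the gap rule
        gaps = rng.choice([40_000, 60_000, 80_000, 1_200_000],
                          p=[0.4, 0.3, 0.25, 0.05], size=int(k))
        chroms[c] = np.cumsum(gaps) + 1
        left -= int(k)
        if left <= 0:
            break
    return make_map({c: p for c, p in chroms.items() if len(p)})


class TestOracleEquivalence:
    """scan_class must equal exhaustive maximal-window enumeration."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_panels(self, seed):
        rng = np.random.default_rng(seed)
        n_markers = int(rng.integers(40, 200))
        m = random_panel(rng, n_markers)
        n = len(m)
        for cls in default_classes():
            for _ in range(3):
                calls = rng.choice(
                    np.array([0, 1, 2, MISSING], dtype=np.int8),
                    p=[0.44, 0.08, 0.44, 0.04], size=n,
                )
                got = segments_as_tuples(scan_class(calls, m, cls))
                expected = brute_force_scan(calls, m, cls)
                assert got == expected


class TestDetectRoh:
    def test_whole_chromosome_run_is_16plus(self):
        # 30 Mb fully homozygous chromosome -> exactly one segment, class 16+
        m = make_map({1: range(1, 30_000_000, 50_000)})
        gm = make_gm([[0] * len(m)])
        segs = detect_roh(gm, m)
        assert len(segs) == 1 and segs[0].class_name == "16+"

    def test_missing_tolerated_run_wins_dedup(self):
        # a 5 Mb run with one missing call: the 4-8 class (1 missing allowed)
        # finds it whole; the zero-missing sub-runs are suppressed
        m = make_map({1: range(1, 101 * 50_000, 50_000)})
        calls = np.zeros(101, dtype=np.int8)
        calls[50] = MISSING
        gm = make_gm([list(calls)])
        segs = detect_roh(gm, m)
        assert len(segs) == 1
        s = segs[0]
        assert s.class_name == "4-8" and s.n_missing == 1
        assert s.start_bp == 1 and s.end_bp == 100 * 50_000 + 1

    def test_overlapping_classes_rejected(self, uniform_map):
        gm = make_gm([[0] * 100])
        bad = [LengthClass("a", 1, 4, 0, 0), LengthClass("b", 2, math.inf, 0, 0)]
        with pytest.raises(ValueError, match="tile"):
            detect_roh(gm, uniform_map, bad)

    def test_planted_tracts_recovered_exactly(self, small_sim):
        _, marker_map, gm, truth = small_sim
        segs = detect_roh(gm, marker_map)
        by_sample = {}
        for s in segs:
            by_sample.setdefault((s.sample_id, s.chrom), []).append(s)
        for t in truth.tracts.itertuples(index=False):
            if t.n_snps < 30 or t.end_bp - t.start_bp < 1_000_000:
                continue
            hits = [
                s for s in by_sample.get((t.sample_id, t.chrom), [])
                if s.start_bp == t.start_bp and s.end_bp == t.end_bp
            ]
            assert hits, f"tract {t} not recovered with exact boundaries"

    def test_dedup_leaves_disjoint_segments(self, small_sim):
        _, marker_map, gm, _ = small_sim
        segs = detect_roh(gm, marker_map)
        by_sample = {}
        for s in segs:
            by_sample.setdefault((s.sample_id, s.chrom), []).append(s)
        for group in by_sample.values():
            group.sort(key=lambda s: s.start_bp)
            for a, b in zip(group, group[1:]):
                assert a.end_bp < b.start_bp

    def test_segments_start_and_end_homozygous(self, small_sim):
        _, marker_map, gm, _ = small_sim
        pos_index = {
            (c, p): i
            for i, (c, p) in enumerate(zip(marker_map.df["chrom"], marker_map.df["pos_bp"]))
        }
        sample_index = {sid: i for i, sid in enumerate(gm.sample_ids)}
        for s in detect_roh(gm, marker_map):
            row = gm.calls[sample_index[s.sample_id]]
            for bp in (s.start_bp, s.end_bp):
                assert row[pos_index[(s.chrom, bp)]] in (0, 2)

    def test_short_planted_tracts_never_reported(self):
        # 1.2 Mb tract of only 25 markers (48 kb fixed spacing): below min_snps
        from rohscan.simulate import SimConfig, TractSpec, generate_map, simulate_panel

        cfg = SimConfig(
            seed=3, n_chrom=1, chrom_span_bp=[40_000_000],
            mean_spacing_bp=48_000, sd_spacing_bp=0, n_individuals=10,
            tract_specs=[TractSpec(frequency=1.0, length_bp=1_180_000)],
            error_rate=0.0, missing_rate=0.0,
        )
        m = generate_map(cfg)
        gm, truth = simulate_panel(cfg, m)
        assert (truth.tracts["n_snps"] < 30).all()
        segs = detect_roh(gm, m)
        for t in truth.tracts.itertuples(index=False):
            for s in segs:
                if s.sample_id == t.sample_id:
                    ov = min(s.end_bp, t.end_bp) - max(s.start_bp, t.start_bp)
                    assert ov < 0.5 * (t.end_bp - t.start_bp)


class TestMonotonicity:
    @given(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_relaxing_allowances_never_decreases_length(self, het, miss, seed):
        # for the open-ended class: larger allowances can only extend runs
        rng = np.random.default_rng(seed)
        m = random_panel(rng, 120, n_chrom=1)
        calls = rng.choice(np.array([0, 1, 2, MISSING], dtype=np.int8),
                           p=[0.46, 0.05, 0.46, 0.03], size=len(m))
        base = LengthClass("1+", 1, math.inf, het, miss)
        relaxed = LengthClass("1+", 1, math.inf, het + 1, miss + 1)
        len_base = sum(s.length_bp for s in scan_class(calls, m, base))
        len_relaxed = sum(s.length_bp for s in scan_class(calls, m, relaxed))
        assert len_relaxed >= len_base


class TestAllowances:
    @pytest.mark.parametrize("expected,rate,result", [
        (0, 0.002, 0),
        (520, 0.002, 1),   # 1.04 -> 1
        (240, 0.002, 0),   # 0.48 -> 0
        (250, 0.002, 1),   # 0.50 rounds half up
        (1000, 0.002, 2),
    ])
    def test_allowed_errors(self, expected, rate, result):
        assert allowed_errors(expected, rate) == result

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            allowed_errors(10, 1.0)

    def test_zero_rate_zeroes_all_allowances(self, small_sim):
        _, marker_map, gm, _ = small_sim
        out = calibrate_allowances(gm, marker_map, error_rate=0.0)
        assert all(c.max_het == 0 for c in out)

    def test_empty_pilot_class_gets_zero(self, uniform_map):
        gm = make_gm([[1] * 100])  # all het: no pilot segments anywhere
        out = calibrate_allowances(gm, uniform_map)
        assert all(c.max_het == 0 for c in out)

    def test_bovine_like_panel_reproduces_allowance_pattern(self):
        # long planted tracts make the 16+ pilot mean exceed 250 SNPs at
        # 55 kb spacing, giving the (0,0,0,0,1) heterozygote pattern
        from rohscan.simulate import SimConfig, TractSpec, generate_map, simulate_panel

        cfg = SimConfig(
            seed=9, n_chrom=3, chrom_span_bp=[90_000_000] * 3, n_individuals=12,
            tract_specs=[
                TractSpec(frequency=1.0, length_bp=(18e6, 40e6)),
                TractSpec(frequency=1.0, length_bp=(1.2e6, 14e6), n_per_carrier=3),
            ],
            error_rate=0.0, missing_rate=0.0,
        )
        m = generate_map(cfg)
        gm, _ = simulate_panel(cfg, m)
        out = calibrate_allowances(gm, m)
        by_name = {c.name: c.max_het for c in out}
        assert by_name["16+"] >= 1
        assert by_name["1-2"] == by_name["2-4"] == by_name["4-8"] == 0


class TestClassValidation:
    def test_default_classes_tile(self):
        validate_classes(default_classes())

    def test_gap_between_classes_rejected(self):
        with pytest.raises(ValueError):
            validate_classes([LengthClass("a", 1, 2, 0, 0),
                              LengthClass("b", 3, math.inf, 0, 0)])

    def test_bounded_last_class_rejected(self):
        with pytest.raises(ValueError):
            validate_classes([LengthClass("a", 1, 16, 0, 0)])
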