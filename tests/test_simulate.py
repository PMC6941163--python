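import numpy as np
import pytest

from rohscan.io import MISSING
from rohscan.roh import RohSegment, detect_roh
from rohscan.simulate import (
    SimConfig,
    TractSpec,
    evaluate_recovery,
    generate_map,
    simulate_panel,
    write_panel,
)


class TestGenerateMap:
    def test_fixed_spacing_positions(self):
        cfg = SimConfig(seed=1, n_chrom=1, chrom_span_bp=[10_000_000],
                        mean_spacing_bp=50_000, sd_spacing_bp=0,
                        n_snps_per_chrom=100)
        m = generate_map(cfg)
        pos = m.df["pos_bp"].to_numpy()
        assert pos[0] == 1 and pos[1] == 50_001
        assert len(pos) == 100

    def test_same_seed_identical_map(self):
        cfg = SimConfig(seed=77, n_chrom=2, chrom_span_bp=[20_000_000] * 2)
        assert generate_map(cfg).df.equals(generate_map(cfg).df)

    def test_span_too_small_rejected(self):
        cfg = SimConfig(seed=1, n_chrom=1, chrom_span_bp=[1_000_000],
                        mean_spacing_bp=50_000, sd_spacing_bp=0,
                        n_snps_per_chrom=100)
        with pytest.raises(ValueError, match="too small"):
            generate_map(cfg)

    def test_empirical_mean_spacing(self):
        cfg = SimConfig(seed=5, n_chrom=1, chrom_span_bp=[700_000_000],
                        n_snps_per_chrom=10_000)
        pos = generate_map(cfg).df["pos_bp"].to_numpy()
        mean_gap = np.diff(pos).mean()
        # truncation at 1 bp lifts the mean slightly above 55.4 kb
        assert abs(mean_gap - 55_400) / 55_400 < 0.05


class TestSimulatePanel:
    def test_planted_tract_forced_homozygous(self):
        cfg = SimConfig(seed=2, n_chrom=1, chrom_span_bp=[30_000_000],
                        mean_spacing_bp=50_000, sd_spacing_bp=0, n_individuals=5,
                        tract_specs=[TractSpec(frequency=1.0, length_bp=3_000_000)],
                        error_rate=0.0, missing_rate=0.0)
        m = generate_map(cfg)
        gm, truth = simulate_panel(cfg, m)
        pos = m.df["pos_bp"].to_numpy()
        for t in truth.tracts.itertuples(index=False):
            i = gm.sample_ids.index(t.sample_id)
            inside = (pos >= t.start_bp) & (pos <= t.end_bp)
            assert np.isin(gm.calls[i][inside], (0, 2)).all()

    def test_error_count_binomial(self):
        cfg = SimConfig(seed=3, n_chrom=2, chrom_span_bp=[60_000_000] * 2,
                        n_individuals=50, error_rate=0.002, missing_rate=0.0)
        m = generate_map(cfg)
        gm, truth = simulate_panel(cfg, m)
        n_hom_before = len(truth.error_coords) + int(((gm.calls == 0) | (gm.calls == 2)).sum())
        n, p = n_hom_before, 0.002
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(truth.error_coords) - n * p) < 3 * sd

    def test_fixed_block_carrier_frequency(self):
        cfg = SimConfig(seed=4, n_chrom=1, chrom_span_bp=[50_000_000],
                        n_individuals=100,
                        tract_specs=[TractSpec(frequency=0.8, length_bp=3_000_000,
                                               placement="fixed")],
                        error_rate=0.0, missing_rate=0.0)
        m = generate_map(cfg)
        _, truth = simulate_panel(cfg, m)
        carriers = truth.tracts["sample_id"].nunique()
        sd = np.sqrt(100 * 0.8 * 0.2)
        assert abs(carriers - 80) < 3 * sd
        # fixed placement: one shared location
        assert truth.tracts[["chrom", "start_bp", "end_bp"]].drop_duplicates().shape[0] == 1

    def test_missingness_applied_and_recorded(self):
        cfg = SimConfig(seed=6, n_chrom=1, chrom_span_bp=[40_000_000],
                        n_individuals=20, error_rate=0.0, missing_rate=0.02)
        m = generate_map(cfg)
        gm, truth = simulate_panel(cfg, m)
        assert int((gm.calls == MISSING).sum()) == len(truth.missing_coords)
        assert len(truth.missing_coords) > 0

    def test_truth_fraction_consistency(self, small_sim):
        _, _, _, truth = small_sim
        df = truth.tracts
        recomputed = (
            (df["end_bp"] - df["start_bp"]).groupby(df["sample_id"]).sum()
            / truth.genome_bp
        )
        per_sample = truth.per_sample_fraction
        for sid, frac in recomputed.items():
            assert per_sample[sid] == pytest.approx(frac)
        assert truth.realized_fraction == pytest.approx(per_sample.mean())

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=11, n_chrom=2, chrom_span_bp=[30_000_000] * 2,
                        n_individuals=5, target_autozygosity=0.05)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_panel(cfg, d1)
        write_panel(cfg, d2)
        for name in ("panel.ped", "panel.map", "truth.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestEvaluateRecovery:
    def truth_and_perfect_calls(self, small_sim):
        _, _, _, truth = small_sim
        segs = [
            RohSegment(t.sample_id, t.chrom, t.start_bp, t.end_bp,
                       t.n_snps, 0, 0, "2-4")
            for t in truth.tracts.itertuples(index=False)
        ]
        return truth, segs

    def test_perfect_calls(self, small_sim):
        truth, segs = self.truth_and_perfect_calls(small_sim)
        rec = evaluate_recovery(truth, segs)
        assert rec.sensitivity == 1.0 and rec.precision == 1.0
        assert (rec.per_tract["start_err"] == 0).all()
        assert (rec.per_tract["end_err"] == 0).all()
        assert (rec.froh_errors == 0).all()

    def test_empty_call_set(self, small_sim):
        truth, _ = self.truth_and_perfect_calls(small_sim)
        rec = evaluate_recovery(truth, [])
        assert rec.sensitivity == 0.0

    def test_end_to_end_noiseless_detection(self, small_sim):
        _, marker_map, gm, truth = small_sim
        segs = detect_roh(gm, marker_map)
        eligible = truth.tracts[
            (truth.tracts["n_snps"] >= 30)
            & (truth.tracts["end_bp"] - truth.tracts["start_bp"] >= 1_000_000)
        ]
        rec = evaluate_recovery(truth, segs)
        det = rec.per_tract.merge(
            eligible, on=["sample_id", "chrom", "start_bp", "end_bp"]
        )
        assert det["detected"].all()


class TestConfigValidation:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, error_rate=1.5)

    def test_span_list_length_checked(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_chrom=3, chrom_span_bp=[1_000_000] * 2)

    def test_default_spans_bovine_scale(self):
        cfg = SimConfig(seed=1)
        assert len(cfg.chrom_span_bp) == 29
        assert 2.4e9 < sum(cfg.chrom_span_bp) < 2.6e9
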