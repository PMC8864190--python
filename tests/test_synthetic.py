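"""Generator tests: genomes, spiked CNV profiles, read simulation, presets."""

import numpy as np
import pytest

from sccnv import (CloneProfile, CNVSegment, NoiseModel, build_genome,
                   simulate_cell_reads, simulate_population,
                   simulate_preset_population, spike_random_cnvs,
                   three_clone_preset)
from sccnv.errors import InvalidArgumentError, PlacementFailureError
from sccnv.simulate import cn_window_track


class TestBuildGenome:
    def test_total_length_is_sum_of_chromosomes(self):
        g = build_genome(3, 50_000_000, seed=0)
        assert g.total_length == 150_000_000
        assert g.n_chroms == 3

    def test_same_seed_reproduces_gc_track(self):
        a = build_genome(2, 5_000_000, seed=7)
        b = build_genome(2, 5_000_000, seed=7)
        np.testing.assert_array_equal(a.gc_track, b.gc_track)

    def test_zero_autocorrelation_gives_independent_windows(self):
        g = build_genome(1, 50_000_000, gc_autocorrelation=0.0, seed=3)
        x = g.gc_track  # 5000 windows
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r) < 0.05

    def test_high_autocorrelation_gives_smooth_track(self):
        g = build_genome(1, 50_000_000, gc_autocorrelation=0.95, seed=3)
        r = np.corrcoef(g.gc_track[:-1], g.gc_track[1:])[0, 1]
        assert r > 0.8

    def test_gc_bounded(self):
        g = build_genome(2, 20_000_000, seed=1)
        assert g.gc_track.min() >= 0.3 and g.gc_track.max() <= 0.7

    @pytest.mark.parametrize("bad", [dict(n_chroms=0, chrom_length_bp=5_000_000),
                                     dict(n_chroms=1, chrom_length_bp=10_000)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            build_genome(**bad)


class TestSpikeRandomCnvs:
    def test_exact_sizes_and_count(self):
        g = build_genome(4, 50_000_000, seed=1)
        prof = spike_random_cnvs(g, 2_000_000, 20, seed=5)
        assert len(prof.segments) == 20
        assert all(s.length == 2_000_000 for s in prof.segments)

    def test_zero_count_gives_empty_profile(self, small_genome):
        assert spike_random_cnvs(small_genome, 2_000_000, 0).segments == []

    def test_union_length_implies_no_overlap(self, small_genome):
        prof = spike_random_cnvs(small_genome, 1_000_000, 15, seed=2)
        by_chrom = {}
        for s in prof.segments:
            by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
        union = 0
        for ivs in by_chrom.values():
            for (a1, b1) in ivs:
                union += b1 - a1
                for (a2, b2) in ivs:
                    if (a1, b1) != (a2, b2):
                        assert b1 <= a2 or a1 >= b2
        assert union == 15 * 1_000_000

    def test_half_genome_precondition(self, small_genome):
        with pytest.raises(InvalidArgumentError):
            spike_random_cnvs(small_genome, 5_000_000, 6)

    def test_dense_placement_failure_reported(self):
        # near-half-genome load with a single attempt per CNV cannot place
        g = build_genome(1, 10_000_000, seed=0)
        with pytest.raises(PlacementFailureError):
            spike_random_cnvs(g, 999_000, 5, seed=0, max_tries_per_cnv=1)

    def test_deterministic(self, small_genome):
        a = spike_random_cnvs(small_genome, 2_000_000, 10, seed=9)
        b = spike_random_cnvs(small_genome, 2_000_000, 10, seed=9)
        assert a.segments == b.segments


class TestSimulateCellReads:
    def test_cn0_segment_emits_no_reads(self, small_genome, clean_noise):
        # deliberately NOT window-aligned: bp-level placement must respect CN=0
        seg = CNVSegment("chr1", 2_004_321, 4_123_456, 0)
        prof = CloneProfile(name="del", segments=[seg])
        rs = simulate_cell_reads(small_genome, prof, 100_000, clean_noise)
        on_chr1 = rs.starts[rs.chrom_idx == 0]
        inside = (on_chr1 >= seg.start) & (on_chr1 < seg.end)
        assert inside.sum() == 0

    def test_poisson_when_dispersion_zero(self, small_genome, diploid, clean_noise):
        rs = simulate_cell_reads(small_genome, diploid, 300_000, clean_noise)
        counts = np.zeros(small_genome.n_windows_total)
        W = small_genome.window_bp
        for c in range(small_genome.n_chroms):
            pos = rs.starts[rs.chrom_idx == c]
            off = int(small_genome.window_offsets[c])
            n = int(small_genome.n_windows[c])
            counts[off:off + n] = np.bincount(pos // W, minlength=n)[:n]
        vmr = counts.var() / counts.mean()
        assert 0.9 <= vmr <= 1.1

    def test_duplicate_fraction_matches_dup_rate(self, small_genome, diploid):
        noise = NoiseModel(gc_bias_strength=0, dispersion=0, dup_rate=0.2, seed=4)
        rs = simulate_cell_reads(small_genome, diploid, 100_000, noise)
        removed = 1 - rs.n_unique() / rs.n_raw
        assert removed == pytest.approx(0.20, abs=0.01)

    def test_read_mass_conservation(self, small_genome, diploid, clean_noise):
        rs = simulate_cell_reads(small_genome, diploid, 1_000_000, clean_noise)
        # Poisson total: relative deviation well under 1%
        assert abs(rs.n_raw - 1_000_000) / 1_000_000 < 0.01

    def test_doubling_cn_doubles_expected_reads(self, small_genome, clean_noise):
        seg2 = CNVSegment("chr2", 0, 8_000_000, 2)
        seg4 = CNVSegment("chr2", 8_000_000, 16_000_000, 4)
        prof = CloneProfile(name="p", segments=[seg2, seg4])
        rs = simulate_cell_reads(small_genome, prof, 1_000_000, clean_noise)
        pos = rs.starts[rs.chrom_idx == 1]
        n2 = np.sum((pos >= 0) & (pos < 8_000_000))
        n4 = np.sum((pos >= 8_000_000) & (pos < 16_000_000))
        assert n4 / n2 == pytest.approx(2.0, rel=0.05)

    def test_reproducible_given_seed(self, small_genome, diploid):
        noise = NoiseModel(seed=123)
        a = simulate_cell_reads(small_genome, diploid, 50_000, noise)
        b = simulate_cell_reads(small_genome, diploid, 50_000, noise)
        np.testing.assert_array_equal(a.starts, b.starts)
        np.testing.assert_array_equal(a.chrom_idx, b.chrom_idx)

    def test_unknown_chromosome_rejected(self, small_genome, clean_noise):
        prof = CloneProfile(name="p", segments=[CNVSegment("chr9", 0, 100, 3)])
        with pytest.raises(InvalidArgumentError):
            simulate_cell_reads(small_genome, prof, 1000, clean_noise)

    def test_cn_track_conserves_segment_mass(self, small_genome):
        # fractional window CN at unaligned boundaries preserves total CN mass
        seg = CNVSegment("chr1", 1_234_567, 3_456_789, 4)
        prof = CloneProfile(name="p", segments=[seg])
        cn = cn_window_track(small_genome, prof)
        W = small_genome.window_bp
        extra = (cn[small_genome.window_slice(0)] - 2).sum() * W
        assert extra == pytest.approx(2 * seg.length, rel=1e-9)


class TestPopulationAndPreset:
    def test_primary_sample_has_106_cells(self, scaled_genome):
        preset = three_clone_preset(scaled_genome)
        noise = NoiseModel(seed=0)
        reads, truth = simulate_preset_population(
            scaled_genome, preset, 2000, noise, seed=5, samples=["primary"])
        assert len(reads) == 106
        assert (truth["sample"] == "primary").all()

    def test_minor_clone_fraction_is_15_5_percent(self, scaled_genome):
        preset = three_clone_preset(scaled_genome)
        assert preset.minor_clone_fraction("primary") == pytest.approx(16 / 103)

    def test_clone_a_is_baseline_on_minor_chroms(self, scaled_genome):
        preset = three_clone_preset(scaled_genome)
        a = preset.clones["A"]
        assert all(s.chrom not in ("chr1", "chr10", "chr14") for s in a.segments)

    def test_normal_clone_has_no_segments(self, scaled_genome):
        assert three_clone_preset(scaled_genome).clones["normal"].segments == []

    def test_minor_clones_carry_1q_10q_14q_events(self, scaled_genome):
        preset = three_clone_preset(scaled_genome)
        for clone in ("B", "C"):
            chroms = {s.chrom for s in preset.clones[clone].segments}
            assert {"chr1", "chr10", "chr14"} <= chroms

    def test_small_genome_rejected(self, small_genome):
        with pytest.raises(InvalidArgumentError):
            three_clone_preset(small_genome)

    def test_empty_population(self, small_genome, diploid, clean_noise):
        reads, truth = simulate_population(small_genome, [diploid], [0],
                                           1000, clean_noise)
        assert reads == [] and len(truth) == 0

    def test_population_deterministic(self, small_genome, diploid):
        noise = NoiseModel(seed=0)
        r1, t1 = simulate_population(small_genome, [diploid], [3], 5000,
                                     noise, seed=77)
        r2, t2 = simulate_population(small_genome, [diploid], [3], 5000,
                                     noise, seed=77)
        assert t1.equals(t2)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.starts, b.starts)
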