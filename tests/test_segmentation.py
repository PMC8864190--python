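"""CBS segmentation and integer copy-number calling.

The independent oracle for CBS split placement is an exhaustive scan of the
pooled-variance t-statistic over every arc (i, j), implemented here with
plain numpy loops, separate from the package's compiled kernels.
"""

import numpy as np
import pytest

from sccnv import (RatioProfile, call_integer_cn, cbs_segment,
                   extract_cnv_calls, make_bins)
from sccnv.binning import BinScheme
from sccnv.errors import DegenerateInputError
from sccnv.segment import CNProfile, SegmentProfile


def flat_scheme(n_bins, bin_bp=30_000, n_chroms=1):
    """Uniform single-width scheme for hand-built ratio tracks."""
    per = [n_bins // n_chroms] * n_chroms
    per[-1] += n_bins - sum(per)
    chroms, starts, ends = [], [], []
    names = [f"chr{i+1}" for i in range(n_chroms)]
    for name, nb in zip(names, per):
        chroms += [name] * nb
        starts += list(np.arange(nb) * bin_bp)
        ends += list((np.arange(nb) + 1) * bin_bp)
    return BinScheme(chrom=np.array(chroms),
                     start=np.array(starts, dtype=np.int64),
                     end=np.array(ends, dtype=np.int64),
                     gc=np.full(n_bins, 0.45),
                     chrom_names=names)


def profile(values, scheme=None, **kw):
    values = np.asarray(values, dtype=float)
    scheme = scheme or flat_scheme(len(values))
    return RatioProfile(cell_id="t", ratios=values, scheme=scheme,
                        enforce_mean=False, **kw)


def oracle_best_arc(x, min_width=2):
    """Exhaustive argmax of the pooled-variance arc t-statistic."""
    n = len(x)
    best = (-1.0, -1, -1)
    for i in range(n):
        for j in range(i + min_width, n + 1):
            m, k = j - i, n - (j - i)
            if k < min_width:
                continue
            arc, rest = x[i:j], np.concatenate([x[:i], x[j:]])
            ss = ((arc - arc.mean()) ** 2).sum() + ((rest - rest.mean()) ** 2).sum()
            var = max(ss / (n - 2), 1e-8)
            t = abs(arc.mean() - rest.mean()) / np.sqrt(var * (1 / m + 1 / k))
            if t > best[0] + 1e-12:
                best = (t, i, j)
    return best


class TestCbsSegment:
    def test_constant_profile_is_one_segment_per_chromosome(self):
        p = profile(np.ones(300), flat_scheme(300, n_chroms=3))
        seg = cbs_segment(p, seed=0)
        assert seg.n_segments == 3
        np.testing.assert_allclose(seg.mean_ratio, 1.0)

    def test_single_step_breakpoint_recovered(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([np.ones(100), np.full(100, 1.5)])
        x += rng.normal(0, 0.05, 200)
        seg = cbs_segment(profile(x), seed=1)
        assert seg.n_segments == 2
        assert abs(int(seg.end_bin[0]) - 100) <= 2

    def test_step_split_matches_oracle_argmax(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([np.ones(30), np.full(20, 1.6)])
        x += rng.normal(0, 0.05, 50)
        _, i, j = oracle_best_arc(x)
        seg = cbs_segment(profile(x), seed=2)
        cuts = set(seg.start_bin) | set(seg.end_bin)
        assert {i, j} - {0, 50} <= cuts

    def test_two_bin_spike_isolated(self):
        rng = np.random.default_rng(3)
        x = 1.0 + rng.normal(0, 0.05, 200)
        x[99:101] += 3.0
        seg = cbs_segment(profile(x), min_width=2, seed=3)
        spans = list(zip(seg.start_bin, seg.end_bin))
        assert (99, 101) in spans

    def test_idempotent_on_noiseless_piecewise_profile(self):
        x = np.concatenate([np.ones(60), np.full(40, 1.5), np.ones(50),
                            np.full(30, 0.5)])
        seg = cbs_segment(profile(x), seed=4)
        assert list(seg.start_bin) == [0, 60, 100, 150]
        assert list(seg.end_bin) == [60, 100, 150, 180]
        np.testing.assert_allclose(seg.mean_ratio, [1.0, 1.5, 1.0, 0.5])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([np.ones(80), np.full(70, 1.5)])
        x += rng.normal(0, 0.05, 150)
        a = cbs_segment(profile(x), seed=5)
        b = cbs_segment(profile(3.0 * x), seed=5)
        np.testing.assert_array_equal(a.start_bin, b.start_bin)
        np.testing.assert_allclose(b.mean_ratio, 3.0 * a.mean_ratio, rtol=1e-12)

    @pytest.mark.parametrize("case_seed", range(6))
    def test_oracle_equivalence_single_changepoint(self, case_seed):
        """On <=50-bin chromosomes the accepted split equals the exhaustive
        all-(i,j) argmax."""
        rng = np.random.default_rng(100 + case_seed)
        cp = int(rng.integers(10, 40))
        n = 50
        x = np.ones(n)
        x[cp:] = 1.0 + rng.choice([-0.6, 0.6])
        x += rng.normal(0, 0.05, n)
        _, i, j = oracle_best_arc(x)
        seg = cbs_segment(profile(x), seed=case_seed)
        cuts = set(seg.start_bin) | set(seg.end_bin)
        assert {i, j} - {0, n} <= cuts

    def test_tiny_chromosome_single_segment_with_warning(self):
        p = profile([1.0], flat_scheme(1))
        with pytest.warns(UserWarning):
            seg = cbs_segment(p, min_width=2, seed=0)
        assert seg.n_segments == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        x = 1.0 + rng.normal(0, 0.3, 150)
        a = cbs_segment(profile(x), seed=6)
        b = cbs_segment(profile(x), seed=6)
        np.testing.assert_array_equal(a.start_bin, b.start_bin)


class TestCallIntegerCn:
    def _segprof(self, bounds, means, scheme):
        return SegmentProfile(cell_id="t",
                              start_bin=np.array(bounds[:-1]),
                              end_bin=np.array(bounds[1:]),
                              mean_ratio=np.array(means, dtype=float),
                              scheme=scheme)

    def test_all_unit_ratios_are_diploid(self):
        scheme = flat_scheme(100)
        cn = call_integer_cn(self._segprof([0, 100], [1.0], scheme))
        assert (cn.cn_per_bin == 2).all()
        assert cn.calls == []

    def test_ratio_1_5_is_cn3(self):
        scheme = flat_scheme(100)
        cn = call_integer_cn(self._segprof([0, 80, 100], [1.0, 1.5], scheme))
        assert (cn.cn_per_bin[80:] == 3).all()

    def test_ratio_0_5_is_cn1(self):
        scheme = flat_scheme(100)
        cn = call_integer_cn(self._segprof([0, 70, 100], [1.0, 0.5], scheme))
        assert (cn.cn_per_bin[70:] == 1).all()

    def test_zero_baseline_degenerate(self):
        scheme = flat_scheme(10)
        with pytest.raises(DegenerateInputError):
            call_integer_cn(self._segprof([0, 10], [0.0], scheme))


class TestExtractCnvCalls:
    def _cnprof(self, cn, scheme):
        return CNProfile(cell_id="t", cn_per_bin=np.array(cn), scheme=scheme)

    def test_diploid_gives_no_calls(self):
        assert extract_cnv_calls(self._cnprof([2] * 50, flat_scheme(50))) == []

    def test_run_merged_into_single_call(self):
        scheme = flat_scheme(5, bin_bp=30_000)
        calls = extract_cnv_calls(self._cnprof([2, 2, 3, 3, 2], scheme))
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end, c.copy_number) == (60_000, 120_000, 3)

    def test_min_size_filter(self):
        scheme = flat_scheme(5, bin_bp=30_000)
        calls = extract_cnv_calls(self._cnprof([2, 2, 3, 3, 2], scheme),
                                  min_size_bp=1_000_000)
        assert calls == []

    def test_calls_do_not_span_chromosomes(self):
        scheme = flat_scheme(40, n_chroms=2)
        cn = [3] * 40  # abnormal everywhere
        calls = extract_cnv_calls(self._cnprof(cn, scheme))
        assert len(calls) == 2
        assert {c.chrom for c in calls} == {"chr1", "chr2"}
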