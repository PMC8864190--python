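"""Circular binary segmentation (CBS) and integer copy-number calling.

CBS recursively looks, within each chromosome, for the arc (i, j) whose bins
differ most from the remaining bins by a pooled-variance t-statistic, and
accepts the split when a within-chromosome permutation test puts its p-value
below ``alpha``.  Accepted splits are refined recursively; afterwards an
"undo" pass merges adjacent segments whose means differ by less than
``undo_sd`` times the MAD of bin-to-bin ratio differences, which removes
splits that are statistically detectable but biologically negligible.

Segment means are then converted to integer copy numbers by scaling against
the length-weighted median segment ratio (the diploid baseline) and rounding.

The statistic operates on untransformed ratios: deep deletions drive ratios
toward 0 where a log transform degenerates.  The permutation kernels are
compiled with numba; permutations stop early once the exceedance count
already decides the test at the requested ``alpha``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .binning import BinScheme, RatioProfile
from .errors import DegenerateInputError, InvalidArgumentError
from .simulate import CNVSegment, MAX_COPY_NUMBER

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8


@njit(cache=False)
def _max_arc_t(x: np.ndarray, min_width: int):
    """Max |t| over all arcs [i, j) with arc and complement >= min_width.

    Returns (t, i, j); ties broken by smallest i then smallest j.  (t, -1, -1)
    when no admissible arc exists.
    """
    n = x.shape[0]
    S = np.empty(n + 1)
    S2 = np.empty(n + 1)
    S[0] = 0.0
    S2[0] = 0.0
    for k in range(n):
        S[k + 1] = S[k] + x[k]
        S2[k + 1] = S2[k] + x[k] * x[k]
    tot, tot2 = S[n], S2[n]
    best_t = -1.0
    best_i, best_j = -1, -1
    for i in range(0, n - min_width + 1):
        jmax = n - max(min_width - i, 0)  # complement (size n-m) >= min_width
        for j in range(i + min_width, jmax + 1):
            m = j - i
            k2 = n - m
            if k2 < min_width:
                continue
            s_in = S[j] - S[i]
            s2_in = S2[j] - S2[i]
            mean_in = s_in / m
            mean_out = (tot - s_in) / k2
            ss = (s2_in - m * mean_in * mean_in) + \
                 ((tot2 - s2_in) - k2 * mean_out * mean_out)
            var = ss / (n - 2) if n > 2 else _VAR_FLOOR
            if var < _VAR_FLOOR:
                var = _VAR_FLOOR
            t = abs(mean_in - mean_out) / np.sqrt(var * (1.0 / m + 1.0 / k2))
            if t > best_t + 1e-12:
                best_t = t
                best_i, best_j = i, j
    return best_t, best_i, best_j


@njit(cache=False)
def _scan_exceeds(x: np.ndarray, min_width: int, t_obs2: float) -> bool:
    """Does any arc of x reach squared statistic >= t_obs2?

    The arc [i, j) and its circular complement share boundaries and
    statistic, so only widths up to n/2 are scanned.  Returns as soon as an
    exceedance is found; small widths (largest null maxima) are scanned
    first.
    """
    n = x.shape[0]
    S = np.empty(n + 1)
    S2 = np.empty(n + 1)
    S[0] = 0.0
    S2[0] = 0.0
    for k in range(n):
        S[k + 1] = S[k] + x[k]
        S2[k + 1] = S2[k] + x[k] * x[k]
    tot, tot2 = S[n], S2[n]
    dof = n - 2 if n > 2 else 1
    wmax = n // 2
    for m in range(min_width, wmax + 1):
        k2 = n - m
        c = 1.0 / m + 1.0 / k2
        for i in range(0, n - m + 1):
            s_in = S[i + m] - S[i]
            s2_in = S2[i + m] - S2[i]
            mean_in = s_in / m
            mean_out = (tot - s_in) / k2
            ss = (s2_in - m * mean_in * mean_in) + \
                 ((tot2 - s2_in) - k2 * mean_out * mean_out)
            var = ss / dof
            if var < _VAR_FLOOR:
                var = _VAR_FLOOR
            d = mean_in - mean_out
            if d * d >= t_obs2 * var * c:
                return True
    return False


@njit(cache=False)
def _perm_pvalue(x: np.ndarray, min_width: int, t_obs: float, nperm: int,
                 alpha: float, seed: int, early_accept_after: int = 300):
    """Permutation p-value of the observed max arc statistic.

    Shuffles the bins of the chromosome piece and checks whether the
    shuffled max arc statistic reaches the observed one.  Stops early when
    the exceedance count already exceeds the alpha budget (split cannot be
    significant), or -- conservatively for clearly significant splits --
    when no exceedance occurred within ``early_accept_after`` permutations.
    """
    np.random.seed(seed)
    y = x.copy()
    reject_at = int(np.ceil(alpha * nperm))
    if reject_at < 1:
        reject_at = 1
    t_obs2 = t_obs * t_obs
    count = 0
    for b in range(nperm):
        np.random.shuffle(y)
        if _scan_exceeds(y, min_width, t_obs2):
            count += 1
            if count >= reject_at:
                return 1.0
        elif count == 0 and b + 1 >= early_accept_after:
            return 0.0
    return count / nperm


@dataclass
class SegmentProfile:
    """Piecewise-constant summary of one cell's ratio profile.

    Segments partition the bin sequence of every chromosome; bin indices are
    global (into the scheme's arrays) and half-open.
    """

    cell_id: str
    start_bin: np.ndarray
    end_bin: np.ndarray
    mean_ratio: np.ndarray
    scheme: BinScheme

    @property
    def n_segments(self) -> int:
        return int(self.start_bin.shape[0])

    def expand_to_bins(self) -> np.ndarray:
        """Per-bin segment mean (the 'segment ratio' track used for clustering)."""
        out = np.empty(self.scheme.n_bins)
        for s, e, m in zip(self.start_bin, self.end_bin, self.mean_ratio):
            out[s:e] = m
        return out

    def chrom_of_segment(self, k: int) -> str:
        return str(self.scheme.chrom[self.start_bin[k]])


@dataclass
class CNProfile:
    """Integer copy number per bin plus discrete CNV calls in bp coordinates."""

    cell_id: str
    cn_per_bin: np.ndarray
    scheme: BinScheme
    baseline: int = 2

    def __post_init__(self) -> None:
        self.cn_per_bin = np.asarray(self.cn_per_bin, dtype=np.int64)
        if np.any(self.cn_per_bin < 0) or np.any(self.cn_per_bin > MAX_COPY_NUMBER):
            raise InvalidArgumentError("cn values outside [0, 12]")

    @property
    def calls(self) -> list[CNVSegment]:
        return extract_cnv_calls(self)

    def abnormal_bin_mask(self) -> np.ndarray:
        return self.cn_per_bin != self.baseline


def _segment_chromosome(x: np.ndarray, alpha: float, nperm: int,
                        min_width: int, rng: np.random.Generator) -> list[int]:
    """Return sorted internal breakpoints (local bin indices) of one chromosome."""
    breaks: list[int] = []
    stack = [(0, x.shape[0])]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2 * min_width:
            continue
        t_obs, i, j = _max_arc_t(x[lo:hi], min_width)
        if i < 0 or t_obs <= 0:
            continue
        seed = int(rng.integers(0, 2 ** 31 - 1))
        p = _perm_pvalue(x[lo:hi], min_width, t_obs, nperm, alpha, seed)
        if p < alpha:
            cuts = sorted({lo + i, lo + j} - {lo, hi})
            for c in cuts:
                breaks.append(c)
            pieces = [lo] + cuts + [hi]
            for a, b in zip(pieces, pieces[1:]):
                stack.append((a, b))
    return sorted(breaks)


def _undo_merge(x: np.ndarray, bounds: list[int], threshold: float) -> list[int]:
    """Merge adjacent segments whose means differ by less than ``threshold``.

    ``bounds`` are local segment boundaries including 0 and n.  Merging is
    iterative, always removing the breakpoint with the smallest mean
    difference first.
    """
    bounds = list(bounds)
    while len(bounds) > 2:
        means = [x[a:b].mean() for a, b in zip(bounds, bounds[1:])]
        diffs = [abs(m2 - m1) for m1, m2 in zip(means, means[1:])]
        k = int(np.argmin(diffs))
        if diffs[k] >= threshold:
            break
        del bounds[k + 1]
    return bounds


def cbs_segment(ratio_profile: RatioProfile,
                alpha: float = 0.01,
                nperm: int = 1000,
                min_width: int = 2,
                undo_sd: float = 1.0,
                seed: int = 0) -> SegmentProfile:
    """Segment a per-bin ratio profile chromosome by chromosome.

    Chromosomes with fewer than ``min_width`` bins are returned as a single
    segment with a warning.  Deterministic given ``seed``.
    """
    x = ratio_profile.ratios
    scheme = ratio_profile.scheme
    rng = np.random.default_rng(seed)

    # noise scale for the undo pass: MAD of within-chromosome bin differences
    diffs = []
    for c in range(len(scheme.chrom_names)):
        sl = scheme.chrom_slice(c)
        if sl.stop - sl.start >= 2:
            diffs.append(np.diff(x[sl]))
    if diffs:
        d = np.concatenate(diffs)
        mad = float(np.median(np.abs(d - np.median(d))))
    else:
        mad = 0.0
    threshold = undo_sd * mad

    starts, ends, means = [], [], []
    for c in range(len(scheme.chrom_names)):
        sl = scheme.chrom_slice(c)
        n = sl.stop - sl.start
        if n == 0:
            continue
        xc = x[sl]
        if n < min_width:
            warnings.warn(f"chromosome {scheme.chrom_names[c]} has {n} bins "
                          f"(< min_width={min_width}); returned unsplit")
            bounds = [0, n]
        else:
            breaks = _segment_chromosome(xc, alpha, nperm, min_width, rng)
            bounds = [0] + breaks + [n]
            if threshold > 0:
                bounds = _undo_merge(xc, bounds, threshold)
        for a, b in zip(bounds, bounds[1:]):
            starts.append(sl.start + a)
            ends.append(sl.start + b)
            means.append(float(xc[a:b].mean()))
    return SegmentProfile(cell_id=ratio_profile.cell_id,
                          start_bin=np.array(starts, dtype=np.int64),
                          end_bin=np.array(ends, dtype=np.int64),
                          mean_ratio=np.array(means, dtype=np.float64),
                          scheme=scheme)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def call_integer_cn(segment_profile: SegmentProfile,
                    assumed_ploidy: int = 2,
                    max_cn: int = MAX_COPY_NUMBER) -> CNProfile:
    """Convert segment mean ratios into integer copy numbers.

    The diploid baseline is the length-weighted median of segment means, so
    the dominant copy-number state maps to ``assumed_ploidy``.  Cells where
    less than 30% of the genome sits at the baseline are flagged: a genome
    that aneuploid may be mis-scaled by a median baseline.
    """
    if segment_profile.n_segments == 0:
        raise DegenerateInputError("segment profile is empty")
    lengths = (segment_profile.end_bin - segment_profile.start_bin).astype(float)
    baseline = _weighted_median(segment_profile.mean_ratio, lengths)
    if baseline <= 0:
        raise DegenerateInputError("baseline segment ratio is zero")
    cn_seg = np.clip(np.round(assumed_ploidy * segment_profile.mean_ratio
                              / baseline), 0, max_cn).astype(np.int64)
    cn = np.empty(segment_profile.scheme.n_bins, dtype=np.int64)
    for s, e, v in zip(segment_profile.start_bin, segment_profile.end_bin, cn_seg):
        cn[s:e] = v
    frac_baseline = lengths[cn_seg == assumed_ploidy].sum() / lengths.sum()
    if frac_baseline < 0.30:
        logger.warning("%s: only %.0f%% of the genome at baseline ploidy; "
                       "integer scaling may be off", segment_profile.cell_id,
                       100 * frac_baseline)
    return CNProfile(cell_id=segment_profile.cell_id, cn_per_bin=cn,
                     scheme=segment_profile.scheme, baseline=assumed_ploidy)


def extract_cnv_calls(cn_profile: CNProfile, min_size_bp: int = 0
                      ) -> list[CNVSegment]:
    """Maximal runs of constant non-baseline copy number, in bp coordinates.

    Runs never span chromosomes; calls shorter than ``min_size_bp`` are
    dropped.
    """
    scheme = cn_profile.scheme
    cn = cn_profile.cn_per_bin
    calls: list[CNVSegment] = []
    for c, name in enumerate(scheme.chrom_names):
        sl = scheme.chrom_slice(c)
        if sl.stop == sl.start:
            continue
        vals = cn[sl]
        change = np.flatnonzero(np.diff(vals)) + 1
        run_starts = np.concatenate([[0], change])
        run_ends = np.concatenate([change, [vals.shape[0]]])
        for a, b in zip(run_starts, run_ends):
            v = int(vals[a])
            if v == cn_profile.baseline:
                continue
            start_bp = int(scheme.start[sl.start + a])
            end_bp = int(scheme.end[sl.start + b - 1])
            if end_bp - start_bp >= min_size_bp:
                calls.append(CNVSegment(name, start_bp, end_bp, v))
    return calls
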