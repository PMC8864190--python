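"""Read binning and GC normalization.

Converts per-cell read start positions into per-bin counts and GC-normalized
copy ratios.  The number of bins follows the usual low-coverage CNV rule of
thumb of 30-180 reads per bin; with ~300,000 deduplicated reads per cell and
a 60-read target this yields 5000 bins.  GC normalization divides counts by
a robust locally weighted (lowess) fit of count against bin GC and rescales
the result to genome-wide mean 1, so a diploid bin has expected ratio 1 and
a single-copy gain ~1.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DegenerateInputError, InvalidArgumentError
from .genome import GenomeModel
from .simulate import ReadSet

logger = logging.getLogger(__name__)

BIN_COUNT_RANGE = (100, 50_000)
TARGET_READS_RANGE = (30, 180)


@dataclass
class BinScheme:
    """An ordered, non-overlapping set of bins tiling a genome."""

    chrom: np.ndarray      # chromosome name per bin
    start: np.ndarray      # int64 bp, 0-based
    end: np.ndarray        # int64 bp, half-open
    gc: np.ndarray         # length-weighted mean GC per bin
    chrom_names: list[str]
    # derived
    chrom_offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.gc = np.asarray(self.gc, dtype=np.float64)
        if not (self.chrom.shape == self.start.shape == self.end.shape
                == self.gc.shape):
            raise InvalidArgumentError("bin arrays must have equal length")
        if np.any(self.end <= self.start):
            raise InvalidArgumentError("bins must have positive width")
        # bins of one chromosome must be contiguous in the arrays
        offsets = [0]
        for name in self.chrom_names:
            n = int(np.sum(self.chrom == name))
            offsets.append(offsets[-1] + n)
        self.chrom_offsets = np.array(offsets, dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return int(self.start.shape[0])

    def chrom_slice(self, chrom_idx: int) -> slice:
        return slice(int(self.chrom_offsets[chrom_idx]),
                     int(self.chrom_offsets[chrom_idx + 1]))

    def bin_ids(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in
                zip(self.chrom, self.start, self.end)]

    def widths(self) -> np.ndarray:
        return self.end - self.start


@dataclass
class BinCounts:
    """Deduplicated read counts per bin for one cell."""

    cell_id: str
    counts: np.ndarray
    n_raw: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")

    @property
    def umdr(self) -> int:
        """Unique mapped deduplicated reads assigned to bins."""
        return int(self.counts.sum())

    @property
    def dup_rate(self) -> float:
        if self.n_raw == 0:
            return 0.0
        return 1.0 - self.umdr / self.n_raw


@dataclass
class RatioProfile:
    """Per-bin GC-normalized copy ratios for one cell (genome mean 1)."""

    cell_id: str
    ratios: np.ndarray
    scheme: BinScheme
    #: pipeline profiles are mean-normalized; set False for raw/scaled tracks
    enforce_mean: bool = True

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=np.float64)
        if np.any(self.ratios < 0):
            raise InvalidArgumentError("ratios must be non-negative")
        if self.enforce_mean and abs(self.ratios.mean() - 1.0) > 1e-6:
            raise InvalidArgumentError("ratios must be normalized to mean 1")


def choose_bin_count(umdr: int, target_reads_per_bin: int = 60) -> int:
    """Bin count from coverage: round(umdr / target), clamped to [100, 50000].

    Targets outside the 30-180 reads-per-bin range are accepted with a
    warning; they fall outside the regime where bin-level CNV calling is
    well powered.
    """
    if umdr <= 0:
        raise InvalidArgumentError("umdr must be positive")
    lo, hi = TARGET_READS_RANGE
    if not lo <= target_reads_per_bin <= hi:
        logger.warning("target_reads_per_bin=%d outside the recommended "
                       "[%d, %d] range", target_reads_per_bin, lo, hi)
    n = int(round(umdr / target_reads_per_bin))
    return int(np.clip(n, *BIN_COUNT_RANGE))


def _allocate(total: int, weights: np.ndarray, minimum: int = 1) -> np.ndarray:
    """Largest-remainder allocation of ``total`` bins proportional to weights."""
    ideal = total * weights / weights.sum()
    base = np.maximum(np.floor(ideal).astype(int), minimum)
    while base.sum() > total:  # minimums may overshoot on tiny totals
        base[np.argmax(base)] -= 1
    rem = total - base.sum()
    if rem > 0:
        frac = ideal - np.floor(ideal)
        for i in np.argsort(-frac)[:rem]:
            base[i] += 1
    return base


def make_bins(genome: GenomeModel,
              n_bins: int,
              weight_track: np.ndarray | None = None) -> BinScheme:
    """Partition the genome into ``n_bins`` bins.

    Without a weight track, bins within a chromosome have equal bp width and
    chromosomes receive bins proportional to their length.  With a per-window
    weight track (an expected read density), bin boundaries instead equalize
    cumulative weight per bin, emulating variable-width binning against a
    read-depth reference.
    """
    if n_bins < genome.n_chroms:
        raise InvalidArgumentError(
            f"n_bins={n_bins} is fewer than the {genome.n_chroms} chromosomes")
    if n_bins > genome.n_windows_total:
        raise InvalidArgumentError("n_bins exceeds the number of GC windows")
    if weight_track is not None:
        weight_track = np.asarray(weight_track, dtype=np.float64)
        if weight_track.shape[0] != genome.n_windows_total:
            raise InvalidArgumentError("weight_track must have one value per window")
        if np.any(weight_track < 0) or weight_track.sum() <= 0:
            raise InvalidArgumentError("weights must be non-negative, not all zero")

    if weight_track is None:
        chrom_w = genome.chrom_lengths.astype(np.float64)
    else:
        widths = np.concatenate([
            genome.window_bounds(c)[1] - genome.window_bounds(c)[0]
            for c in range(genome.n_chroms)]).astype(np.float64)
        per_window_mass = weight_track * widths / genome.window_bp
        chrom_w = np.array([per_window_mass[genome.window_slice(c)].sum()
                            for c in range(genome.n_chroms)])
    alloc = _allocate(n_bins, chrom_w)

    chroms, starts, ends, gcs = [], [], [], []
    for c in range(genome.n_chroms):
        L = int(genome.chrom_lengths[c])
        nb = int(alloc[c])
        if weight_track is None:
            edges = np.round(np.linspace(0, L, nb + 1)).astype(np.int64)
        else:
            w_starts, w_ends = genome.window_bounds(c)
            mass = (weight_track[genome.window_slice(c)]
                    * (w_ends - w_starts) / genome.window_bp)
            cum = np.concatenate([[0.0], np.cumsum(mass)])
            targets = np.linspace(0, cum[-1], nb + 1)
            bp_nodes = np.concatenate([w_starts, [L]]).astype(np.float64)
            edges = np.round(np.interp(targets, cum, bp_nodes)).astype(np.int64)
            edges[0], edges[-1] = 0, L
            edges = np.maximum.accumulate(edges)
            # guarantee positive widths even under degenerate weights
            for i in range(1, nb + 1):
                if edges[i] <= edges[i - 1]:
                    edges[i] = edges[i - 1] + 1
            edges = np.minimum(edges, L)
            if edges[-1] != L:
                edges[-1] = L
        chroms.extend([genome.chrom_names[c]] * nb)
        starts.append(edges[:-1])
        ends.append(edges[1:])
        gcs.append(genome.mean_gc(c, edges[:-1], edges[1:]))
    return BinScheme(chrom=np.array(chroms),
                     start=np.concatenate(starts),
                     end=np.concatenate(ends),
                     gc=np.concatenate(gcs),
                     chrom_names=list(genome.chrom_names))


def count_reads(readset: ReadSet, scheme: BinScheme, dedup: bool = True) -> BinCounts:
    """Assign reads to the bin containing their start position.

    PCR duplicates -- reads sharing an exact (chrom, start) within the cell
    -- are collapsed to one read when ``dedup`` is set.  Reads on chromosomes
    absent from the scheme are dropped and logged.
    """
    rs = readset.deduplicated() if dedup else readset
    counts = np.zeros(scheme.n_bins, dtype=np.int64)
    dropped = 0
    for c, name in enumerate(scheme.chrom_names):
        sel = rs.chrom_idx == c
        if not sel.any():
            continue
        sl = scheme.chrom_slice(c)
        if sl.stop == sl.start:
            dropped += int(sel.sum())
            continue
        pos = rs.starts[sel]
        edges = np.concatenate([scheme.start[sl], [scheme.end[sl.stop - 1]]])
        idx = np.searchsorted(edges, pos, side="right") - 1
        inside = (idx >= 0) & (idx < sl.stop - sl.start) & (pos < edges[-1])
        dropped += int((~inside).sum())
        np.add.at(counts, sl.start + idx[inside], 1)
    known = set(range(len(scheme.chrom_names)))
    unknown = int(np.sum(~np.isin(rs.chrom_idx, list(known))))
    if unknown:
        dropped += unknown
        logger.warning("%s: %d reads on chromosomes unknown to the bin scheme",
                       readset.cell_id, unknown)
    if dropped:
        logger.info("%s: dropped %d reads outside bins", readset.cell_id, dropped)
    return BinCounts(cell_id=readset.cell_id, counts=counts,
                     n_raw=readset.n_raw, n_dropped=dropped)


def gc_normalize(bincounts: BinCounts, scheme: BinScheme,
                 span: float = 0.3) -> RatioProfile:
    """Remove the GC dependence of bin counts by robust lowess regression.

    Fits count vs bin GC with 3 robustifying iterations, divides each count
    by the fitted value (floored at 1e-6 x mean count), and rescales the
    ratios to genome-wide mean 1.  Bins inside large CNVs act as outliers to
    the fit; the robustifying iterations down-weight them.  When more than
    30% of bins deviate more than two-fold from the median a note is logged,
    since plain GC normalization is then operating far from its diploid
    assumption.
    """
    counts = bincounts.counts.astype(np.float64)
    if counts.shape[0] < 50:
        raise InvalidArgumentError("need at least 50 bins for GC normalization")
    if bincounts.umdr < 1000:
        raise InvalidArgumentError("need at least 1000 reads for GC normalization")
    if counts.sum() == 0:
        raise DegenerateInputError("all bin counts are zero")

    gc = scheme.gc
    delta = 0.01 * (gc.max() - gc.min())
    fit = lowess(counts, gc, frac=span, it=3, delta=delta,
                 return_sorted=False)
    eps = 1e-6 * counts.mean()
    ratios = counts / np.maximum(fit, eps)
    ratios = np.maximum(ratios, 0.0)
    med = np.median(counts)
    if med > 0 and np.mean((counts > 2 * med) | (counts < 0.5 * med)) > 0.30:
        logger.info("%s: >30%% of bins deviate >2-fold; GC fit may be biased "
                    "by aneuploidy", bincounts.cell_id)
    ratios /= ratios.mean()
    return RatioProfile(cell_id=bincounts.cell_id, ratios=ratios, scheme=scheme)
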