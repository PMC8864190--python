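"""Synthetic reference genomes with a per-window GC track.

A :class:`GenomeModel` is the minimal stand-in for a real reference that the
count-level pipeline needs: chromosome names and lengths, plus the GC fraction
of fixed-width windows (default 10 kb).  The GC track drives both the
simulated amplification bias and its removal during normalization, so it is
generated as a bounded autocorrelated random walk to mimic the long-range GC
structure of mammalian genomes.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: hg19 autosome lengths in bp (chr1..chr22).
HG19_AUTOSOME_LENGTHS = (
    249250621, 243199373, 198022430, 191154276, 180915260, 171115067,
    159138663, 146364022, 141213431, 135534747, 135006516, 133851895,
    115169878, 107349540, 102531392, 90354753, 81195210, 78077248,
    59128983, 63025520, 48129895, 51304566,
)

DEFAULT_WINDOW_BP = 10_000
GC_RANGE = (0.3, 0.7)


@dataclass
class GenomeModel:
    """A reference genome reduced to chromosome lengths and a GC track.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers, e.g. ``["chr1", ...]``.
    chrom_lengths
        Length of each chromosome in bp.
    window_bp
        Width of the fixed GC windows; the last window of a chromosome may be
        shorter.
    gc_track
        GC fraction per window, concatenated chromosome by chromosome.
    """

    chrom_names: list[str]
    chrom_lengths: np.ndarray
    window_bp: int
    gc_track: np.ndarray
    # derived, filled in __post_init__
    n_windows: np.ndarray = field(init=False, repr=False)
    window_offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        self.gc_track = np.asarray(self.gc_track, dtype=np.float64)
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise InvalidArgumentError("chrom_names and chrom_lengths differ in length")
        if np.any(self.chrom_lengths <= 0):
            raise InvalidArgumentError("chromosome lengths must be positive")
        self.n_windows = -(-self.chrom_lengths // self.window_bp)  # ceil div
        self.window_offsets = np.concatenate([[0], np.cumsum(self.n_windows)])
        if self.gc_track.shape[0] != self.window_offsets[-1]:
            raise InvalidArgumentError(
                f"gc_track has {self.gc_track.shape[0]} windows, expected "
                f"{self.window_offsets[-1]}"
            )
        if np.any(self.gc_track < 0) or np.any(self.gc_track > 1):
            raise InvalidArgumentError("GC fractions must lie in [0, 1]")
        self._index = {name: i for i, name in enumerate(self.chrom_names)}

    # -- basic queries -----------------------------------------------------

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def total_length(self) -> int:
        return int(self.chrom_lengths.sum())

    @property
    def n_windows_total(self) -> int:
        return int(self.window_offsets[-1])

    def chrom_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise InvalidArgumentError(f"unknown chromosome {name!r}") from None

    def window_slice(self, chrom_idx: int) -> slice:
        """Slice of the concatenated window arrays covering one chromosome."""
        return slice(int(self.window_offsets[chrom_idx]),
                     int(self.window_offsets[chrom_idx + 1]))

    def window_bounds(self, chrom_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) in bp of the windows of one chromosome."""
        n = int(self.n_windows[chrom_idx])
        starts = np.arange(n, dtype=np.int64) * self.window_bp
        ends = np.minimum(starts + self.window_bp, self.chrom_lengths[chrom_idx])
        return starts, ends

    def gc_cumulative(self, chrom_idx: int) -> np.ndarray:
        """Cumulative GC mass (gc * bp) at window boundaries of a chromosome.

        Lets callers compute the exact length-weighted mean GC of any bp
        interval by linear interpolation within windows.
        """
        starts, ends = self.window_bounds(chrom_idx)
        gc = self.gc_track[self.window_slice(chrom_idx)]
        return np.concatenate([[0.0], np.cumsum(gc * (ends - starts))])

    def mean_gc(self, chrom_idx: int, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Length-weighted mean GC of the intervals [start, end) on a chromosome."""
        cum = self.gc_cumulative(chrom_idx)
        starts, _ = self.window_bounds(chrom_idx)
        gc = self.gc_track[self.window_slice(chrom_idx)]
        W = self.window_bp

        def interp(pos: np.ndarray) -> np.ndarray:
            w = np.minimum(pos // W, len(gc) - 1).astype(np.int64)
            return cum[w] + gc[w] * (pos - starts[w])

        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        return (interp(end) - interp(start)) / np.maximum(end - start, 1)


def _gc_walk(n: int, autocorr: float, rng: np.random.Generator,
             mean: float = 0.5, sd: float = 0.06) -> np.ndarray:
    """AR(1) series mapped to a GC fraction, clipped to GC_RANGE."""
    eps = rng.standard_normal(n)
    x = np.empty(n)
    if n == 0:
        return x
    x[0] = eps[0]
    a = float(autocorr)
    scale = np.sqrt(max(1.0 - a * a, 0.0))
    for i in range(1, n):
        x[i] = a * x[i - 1] + scale * eps[i]
    return np.clip(mean + sd * x, *GC_RANGE)


def build_genome(n_chroms: int,
                 chrom_length_bp: int | list[int],
                 gc_autocorrelation: float = 0.9,
                 seed: int = 0,
                 window_bp: int = DEFAULT_WINDOW_BP) -> GenomeModel:
    """Build a synthetic genome with an autocorrelated GC track.

    Parameters
    ----------
    n_chroms
        Number of chromosomes (>= 1).
    chrom_length_bp
        A single length applied to every chromosome, or one length per
        chromosome.  Each must be at least 1 Mb so that Mb-scale CNVs and
        kb-scale bins remain meaningful.
    gc_autocorrelation
        Lag-1 autocorrelation of the window GC series; 0 gives independent
        windows.
    """
    if n_chroms < 1:
        raise InvalidArgumentError("n_chroms must be >= 1")
    if np.isscalar(chrom_length_bp):
        lengths = [int(chrom_length_bp)] * n_chroms
    else:
        lengths = [int(x) for x in chrom_length_bp]
        if len(lengths) != n_chroms:
            raise InvalidArgumentError("need one length per chromosome")
    if any(l < 1_000_000 for l in lengths):
        raise InvalidArgumentError("chromosome lengths must be >= 1 Mb")
    if not 0.0 <= gc_autocorrelation < 1.0:
        raise InvalidArgumentError("gc_autocorrelation must be in [0, 1)")

    rng = np.random.default_rng(seed)
    tracks = []
    for L in lengths:
        n = -(-L // window_bp)
        tracks.append(_gc_walk(n, gc_autocorrelation, rng))
    return GenomeModel(
        chrom_names=[f"chr{i + 1}" for i in range(n_chroms)],
        chrom_lengths=np.array(lengths, dtype=np.int64),
        window_bp=window_bp,
        gc_track=np.concatenate(tracks),
    )


def hg19_scaled_genome(scale: int = 20,
                       gc_autocorrelation: float = 0.9,
                       seed: int = 0,
                       window_bp: int = DEFAULT_WINDOW_BP) -> GenomeModel:
    """22 autosomes with hg19-proportional lengths divided by ``scale``.

    ``scale=20`` (~150 Mb total) keeps desk-scale analyses with thousands of
    bins meaningful; ``scale=1`` reproduces full autosome lengths (~2.9 Gb)
    for benchmarks that must place many multi-Mb CNVs.
    """
    lengths = [max(int(l // scale), 1_000_000) for l in HG19_AUTOSOME_LENGTHS]
    return build_genome(22, lengths, gc_autocorrelation=gc_autocorrelation,
                        seed=seed, window_bp=window_bp)
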