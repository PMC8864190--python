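"""Simulation of clonal karyotypes and noisy per-cell read data.

The generator works at the level of read counts, not base sequence: a cell's
reads are drawn window by window with expected mass proportional to
``copy_number x gc_weight(gc)``, with negative-binomial overdispersion, then a
configurable fraction of PCR duplicates (exact position copies) is appended.
This captures the count-level properties that drive low-coverage single-cell
CNV calling -- coverage proportional to copy number, GC amplification bias,
bin-level noise and duplication -- while deliberately ignoring alignment-level
artifacts such as mappability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, PlacementFailureError
from .genome import GenomeModel

logger = logging.getLogger(__name__)

MAX_COPY_NUMBER = 12

#: Window-level negative-binomial overdispersion (var = mu + dispersion*mu^2)
#: calibrated once by bisection so that a diploid cell sequenced to 4e5 raw
#: reads and profiled in 5000 bins on the default (1/20-scale) genome has
#: MAPD ~ 0.26, the noise level of a good-quality tagmentation-based
#: single-cell library.
DEFAULT_DISPERSION = 0.22
DEFAULT_GC_BIAS = 2.0
DEFAULT_DUP_RATE = 0.10


@dataclass(frozen=True)
class CNVSegment:
    """A genomic interval with an integer copy number (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise InvalidArgumentError(
                f"bad segment bounds {self.chrom}:{self.start}-{self.end}")
        if not 0 <= self.copy_number <= MAX_COPY_NUMBER:
            raise InvalidArgumentError(
                f"copy_number {self.copy_number} outside [0, {MAX_COPY_NUMBER}]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CloneProfile:
    """A clone's karyotype: non-overlapping CNV segments over a diploid baseline."""

    name: str
    segments: list[CNVSegment] = field(default_factory=list)
    baseline_cn: int = 2

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CNVSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise InvalidArgumentError(
                        f"overlapping segments on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}")
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))

    def validate_against(self, genome: GenomeModel) -> None:
        for seg in self.segments:
            c = genome.chrom_index(seg.chrom)  # raises for unknown chrom
            if seg.end > genome.chrom_lengths[c]:
                raise InvalidArgumentError(
                    f"segment {seg.chrom}:{seg.start}-{seg.end} exceeds "
                    f"chromosome length {genome.chrom_lengths[c]}")

    def cn_at(self, chrom: str, pos: int) -> int:
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.copy_number
        return self.baseline_cn


@dataclass(frozen=True)
class NoiseModel:
    """Knobs of the count-level noise process.

    gc_bias_strength
        Coefficient of the quadratic GC preference curve
        ``w(gc) = 1 - strength * (gc - 0.5)^2`` (floored at 0.05); 0 disables
        GC bias.
    dispersion
        Negative-binomial overdispersion, ``var = mu + dispersion * mu^2``;
        0 gives Poisson counts.
    dup_rate
        Fraction of the final raw reads that are exact PCR duplicates.
    """

    gc_bias_strength: float = DEFAULT_GC_BIAS
    dispersion: float = DEFAULT_DISPERSION
    dup_rate: float = DEFAULT_DUP_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dup_rate < 1.0:
            raise InvalidArgumentError("dup_rate must be in [0, 1)")
        if self.dispersion < 0:
            raise InvalidArgumentError("dispersion must be >= 0")


@dataclass
class ReadSet:
    """Per-cell aligned read start positions (duplicates included)."""

    cell_id: str
    chrom_idx: np.ndarray  # int32, index into genome.chrom_names
    starts: np.ndarray     # int64 bp
    sample_label: str = "sample"

    @property
    def n_raw(self) -> int:
        return int(self.starts.shape[0])

    def unique_keys(self) -> np.ndarray:
        """Sorted int64 keys identifying distinct (chrom, start) positions."""
        keys = self.chrom_idx.astype(np.int64) * (1 << 40) + self.starts
        return np.unique(keys)

    def n_unique(self) -> int:
        return int(self.unique_keys().shape[0])

    def deduplicated(self) -> "ReadSet":
        keys = self.unique_keys()
        return ReadSet(
            cell_id=self.cell_id,
            chrom_idx=(keys >> 40).astype(np.int32),
            starts=(keys & ((1 << 40) - 1)).astype(np.int64),
            sample_label=self.sample_label,
        )

    def subsample_unique(self, n: int, rng: np.random.Generator) -> "ReadSet":
        """Down-sample without replacement from the unique reads."""
        keys = self.unique_keys()
        if n > keys.shape[0]:
            raise InvalidArgumentError(
                f"cannot sample {n} from {keys.shape[0]} unique reads")
        pick = rng.choice(keys.shape[0], size=n, replace=False)
        keys = keys[np.sort(pick)]
        return ReadSet(
            cell_id=self.cell_id,
            chrom_idx=(keys >> 40).astype(np.int32),
            starts=(keys & ((1 << 40) - 1)).astype(np.int64),
            sample_label=self.sample_label,
        )


def gc_weight(gc: np.ndarray, strength: float) -> np.ndarray:
    """Unimodal GC preference curve centered at 0.5, floored at 0.05."""
    return np.maximum(1.0 - strength * (np.asarray(gc) - 0.5) ** 2, 0.05)


def cn_window_track(genome: GenomeModel, profile: CloneProfile) -> np.ndarray:
    """Length-weighted mean copy number per genome window."""
    profile.validate_against(genome)
    cn = np.full(genome.n_windows_total, float(profile.baseline_cn))
    W = genome.window_bp
    for seg in profile.segments:
        c = genome.chrom_index(seg.chrom)
        off = int(genome.window_offsets[c])
        delta = seg.copy_number - profile.baseline_cn
        w0, w1 = seg.start // W, (seg.end - 1) // W
        # full interior windows
        if w1 > w0 + 1:
            cn[off + w0 + 1: off + w1] += delta
        starts, ends = genome.window_bounds(c)
        for w in {w0, w1}:
            ws, we = int(starts[w]), int(ends[w])
            ov = min(we, seg.end) - max(ws, seg.start)
            if w0 == w1 and w == w0:
                cn[off + w] += delta * ov / (we - ws)
            elif w == w0 != w1:
                cn[off + w] += delta * ov / (we - ws)
            elif w == w1 != w0:
                cn[off + w] += delta * ov / (we - ws)
    return cn


def spike_random_cnvs(genome: GenomeModel,
                      size_bp: int,
                      count: int,
                      seed: int = 0,
                      cn_choices: tuple[int, ...] = (1, 3),
                      max_tries_per_cnv: int = 10_000) -> CloneProfile:
    """Place ``count`` non-overlapping CNVs of exactly ``size_bp`` uniformly.

    Copy numbers are drawn from ``cn_choices`` (default one-copy loss or
    one-copy gain).  Placement is rejection sampling: chromosome chosen with
    probability proportional to the number of valid start positions, start
    uniform, retry on overlap.
    """
    if count < 0:
        raise InvalidArgumentError("count must be >= 0")
    if count == 0:
        return CloneProfile(name=f"spike_{size_bp}bp_x0", segments=[])
    if size_bp < 1:
        raise InvalidArgumentError("size_bp must be >= 1")
    if count * size_bp >= 0.5 * genome.total_length:
        raise InvalidArgumentError(
            f"{count} CNVs of {size_bp} bp exceed half the genome "
            f"({genome.total_length} bp)")

    rng = np.random.default_rng(seed)
    valid = np.maximum(genome.chrom_lengths - size_bp + 1, 0)
    if valid.sum() == 0:
        raise InvalidArgumentError("no chromosome can hold a CNV of this size")
    probs = valid / valid.sum()
    placed: dict[int, list[tuple[int, int]]] = {}
    segments: list[CNVSegment] = []
    for _ in range(count):
        for _attempt in range(max_tries_per_cnv):
            c = int(rng.choice(genome.n_chroms, p=probs))
            start = int(rng.integers(0, valid[c]))
            end = start + size_bp
            if all(end <= s or start >= e for s, e in placed.get(c, [])):
                placed.setdefault(c, []).append((start, end))
                cn = int(rng.choice(cn_choices))
                segments.append(CNVSegment(genome.chrom_names[c], start, end, cn))
                break
        else:
            raise PlacementFailureError(
                f"could not place CNV {len(segments) + 1}/{count} of "
                f"{size_bp} bp after {max_tries_per_cnv} tries")
    return CloneProfile(name=f"spike_{size_bp}bp_x{count}", segments=segments)


def _piecewise_cn(profile: CloneProfile, chrom: str, chrom_len: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(starts, ends, cn) pieces tiling one chromosome."""
    segs = [s for s in profile.segments if s.chrom == chrom]
    starts, ends, cns = [], [], []
    pos = 0
    for s in segs:
        if s.start > pos:
            starts.append(pos); ends.append(s.start); cns.append(profile.baseline_cn)
        starts.append(s.start); ends.append(s.end); cns.append(s.copy_number)
        pos = s.end
    if pos < chrom_len:
        starts.append(pos); ends.append(chrom_len); cns.append(profile.baseline_cn)
    return (np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64),
            np.array(cns, dtype=np.float64))


def simulate_cell_reads(genome: GenomeModel,
                        profile: CloneProfile,
                        n_reads: int,
                        noise: NoiseModel,
                        cell_id: str = "cell",
                        sample_label: str = "sample") -> ReadSet:
    """Simulate one cell's raw read starts.

    ``n_reads`` is the expected number of template (pre-duplication) reads;
    after appending exact-position duplicates the raw total is approximately
    ``n_reads / (1 - dup_rate)`` so that position-based deduplication removes
    a ``dup_rate`` fraction.

    Per window, counts are negative-binomial with mean proportional to
    ``copy_number x gc_weight``; read starts are uniform within the window
    except where a window straddles a copy-number boundary, in which case the
    position density follows the bp-level copy number (a CN=0 stretch emits
    no reads).
    """
    if n_reads < 1:
        raise InvalidArgumentError("n_reads must be >= 1")
    rng = np.random.default_rng(noise.seed)

    cn = cn_window_track(genome, profile)
    w_starts = np.concatenate([genome.window_bounds(c)[0] for c in range(genome.n_chroms)])
    w_ends = np.concatenate([genome.window_bounds(c)[1] for c in range(genome.n_chroms)])
    w_chrom = np.repeat(np.arange(genome.n_chroms, dtype=np.int32), genome.n_windows)
    widths = (w_ends - w_starts).astype(np.float64)

    mass = cn * gc_weight(genome.gc_track, noise.gc_bias_strength) * (widths / genome.window_bp)
    total = mass.sum()
    if total <= 0:
        raise InvalidArgumentError("profile has zero read mass everywhere")
    mu = n_reads * mass / total

    d = noise.dispersion
    if d == 0:
        counts = rng.poisson(mu)
    else:
        counts = np.zeros_like(mu, dtype=np.int64)
        pos_mask = mu > 0
        r = 1.0 / d
        p = r / (r + mu[pos_mask])
        counts[pos_mask] = rng.negative_binomial(r, p)

    # uniform starts within each window
    reps = counts.astype(np.int64)
    chrom_idx = np.repeat(w_chrom, reps)
    lo = np.repeat(w_starts, reps)
    span = np.repeat((w_ends - w_starts), reps)
    starts = lo + (rng.random(lo.shape[0]) * span).astype(np.int64)

    # re-place reads of windows that straddle a copy-number boundary so that
    # the bp-level density follows the profile exactly (CN=0 gets no reads)
    boundary_windows = _mixed_windows(genome, profile)
    if boundary_windows:
        win_of_read = np.repeat(np.arange(mass.shape[0]), reps)
        for widx, (c, pieces) in boundary_windows.items():
            sel = np.flatnonzero(win_of_read == widx)
            if sel.size == 0:
                continue
            ps, pe, pcn = pieces
            weights = pcn * (pe - ps)
            if weights.sum() <= 0:
                # window is effectively CN 0; drop its reads
                keep = np.ones(starts.shape[0], dtype=bool)
                keep[sel] = False
                chrom_idx, starts = chrom_idx[keep], starts[keep]
                continue
            pick = rng.choice(len(ps), size=sel.size, p=weights / weights.sum())
            starts[sel] = ps[pick] + (rng.random(sel.size) * (pe[pick] - ps[pick])).astype(np.int64)

    # PCR duplicates: exact copies of existing reads
    n_base = starts.shape[0]
    if noise.dup_rate > 0 and n_base > 0:
        n_dup = int(round(n_base * noise.dup_rate / (1.0 - noise.dup_rate)))
        if n_dup > 0:
            src = rng.integers(0, n_base, size=n_dup)
            chrom_idx = np.concatenate([chrom_idx, chrom_idx[src]])
            starts = np.concatenate([starts, starts[src]])

    order = np.lexsort((starts, chrom_idx))
    return ReadSet(cell_id=cell_id, chrom_idx=chrom_idx[order],
                   starts=starts[order], sample_label=sample_label)


def _mixed_windows(genome: GenomeModel, profile: CloneProfile
                   ) -> dict[int, tuple[int, tuple[np.ndarray, np.ndarray, np.ndarray]]]:
    """Windows overlapping >1 distinct copy-number piece, with their pieces
    clipped to the window."""
    out: dict[int, tuple[int, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    W = genome.window_bp
    for chrom in {s.chrom for s in profile.segments}:
        c = genome.chrom_index(chrom)
        L = int(genome.chrom_lengths[c])
        ps, pe, pcn = _piecewise_cn(profile, chrom, L)
        # boundaries interior to the chromosome
        for b in ps[1:]:
            w = int(b // W)
            if b % W == 0:
                continue  # boundary coincides with a window edge
            widx = int(genome.window_offsets[c]) + w
            ws = w * W
            we = min(ws + W, L)
            sel = (pe > ws) & (ps < we)
            out[widx] = (c, (np.maximum(ps[sel], ws), np.minimum(pe[sel], we),
                             pcn[sel]))
    return out


def simulate_population(genome: GenomeModel,
                        profiles: list[CloneProfile],
                        cells_per_profile: list[int],
                        n_reads_per_cell: int,
                        noise: NoiseModel,
                        seed: int = 0,
                        sample_labels: list[str] | None = None,
                        cell_id_prefix: str = "") -> tuple[list[ReadSet], "pd.DataFrame"]:
    """Simulate a population of cells; per-cell seeds derive from ``seed``.

    Returns the list of ReadSets and a truth table (cell_id, clone, sample).
    """
    import pandas as pd

    if len(profiles) != len(cells_per_profile):
        raise InvalidArgumentError("profiles and cells_per_profile differ in length")
    if sample_labels is None:
        sample_labels = ["sample"] * len(profiles)
    reads: list[ReadSet] = []
    truth_rows = []
    cell_no = 0
    for prof, n_cells, sample in zip(profiles, cells_per_profile, sample_labels):
        for _ in range(n_cells):
            cell_seed = int(np.random.SeedSequence((seed, cell_no)).generate_state(1)[0] % (2 ** 31))
            cell_noise = NoiseModel(gc_bias_strength=noise.gc_bias_strength,
                                    dispersion=noise.dispersion,
                                    dup_rate=noise.dup_rate, seed=cell_seed)
            cell_id = f"{cell_id_prefix}{sample}_{prof.name}_{cell_no:04d}"
            reads.append(simulate_cell_reads(genome, prof, n_reads_per_cell,
                                             cell_noise, cell_id=cell_id,
                                             sample_label=sample))
            truth_rows.append({"cell_id": cell_id, "clone": prof.name,
                               "sample": sample})
            cell_no += 1
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "clone", "sample"])
    return reads, truth
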