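"""Per-cell quality metrics: MAPD, duplication, Lorenz uniformity, filtering.

MAPD (median absolute pairwise difference) is the median of |r[i+1] - r[i]|
over consecutive within-chromosome bin pairs of the GC-normalized ratio
track.  It measures bin-to-bin amplification noise independently of genuine
copy-number structure, whose contribution to consecutive differences is
limited to the few bins at segment boundaries.  Cells are filtered on
UMDR >= 300,000 and MAPD <= 0.45 (both boundaries inclusive).

Amplification uniformity is summarized by the Lorenz curve of read counts in
fixed 60-kb bins after down-sampling to 100,000 unique reads: cumulative
read fraction against cumulative genome fraction with bins sorted by
ascending count.  The diagonal is a perfectly uniform genome; the Gini
coefficient is twice the area between the curve and the diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .binning import RatioProfile
from .errors import DegenerateInputError
from .genome import GenomeModel
from .simulate import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_UMDR_MIN = 300_000
DEFAULT_MAPD_MAX = 0.45
LORENZ_BIN_BP = 60_000
LORENZ_SAMPLE = 100_000


@dataclass
class CellQC:
    """QC summary of one cell."""

    cell_id: str
    n_raw: int
    umdr: int
    dup_rate: float
    mapd: float
    passed: bool = False
    fail_reason: str = ""


@dataclass
class LorenzCurve:
    """Cumulative genome vs read share over count-sorted bins, plus Gini."""

    cum_genome_fraction: np.ndarray
    cum_read_fraction: np.ndarray
    gini: float


def mapd(ratio_profile: RatioProfile, log2_scale: bool = False) -> float:
    """Median absolute difference of consecutive within-chromosome ratios.

    ``log2_scale`` computes the metric on log2 ratios instead (an alternative
    reading used by some platforms); zero ratios are floored at 1e-3 there.
    """
    x = ratio_profile.ratios
    scheme = ratio_profile.scheme
    if log2_scale:
        x = np.log2(np.maximum(x, 1e-3))
    diffs = []
    for c in range(len(scheme.chrom_names)):
        sl = scheme.chrom_slice(c)
        if sl.stop - sl.start >= 2:
            diffs.append(np.abs(np.diff(x[sl])))
    if not diffs:
        raise DegenerateInputError("no chromosome has >= 2 bins")
    return float(np.median(np.concatenate(diffs)))


def lorenz(readset: ReadSet, genome: GenomeModel,
           bin_size: int = LORENZ_BIN_BP,
           n_sample: int = LORENZ_SAMPLE,
           seed: int = 0) -> LorenzCurve:
    """Lorenz curve of coverage uniformity from down-sampled unique reads.

    Duplicates are removed, reads are down-sampled without replacement to
    ``n_sample`` (all reads used, with a warning, when fewer are available),
    and counts are taken in fixed ``bin_size`` bins tiling the genome.
    """
    if readset.n_raw == 0:
        raise DegenerateInputError("empty read set")
    rng = np.random.default_rng(seed)
    unique = readset.deduplicated()
    if unique.n_raw < n_sample:
        logger.warning("%s: only %d unique reads (< %d); using all",
                       readset.cell_id, unique.n_raw, n_sample)
        sampled = unique
    else:
        sampled = unique.subsample_unique(n_sample, rng)

    counts = []
    for c in range(genome.n_chroms):
        nb = int(-(-genome.chrom_lengths[c] // bin_size))
        pos = sampled.starts[sampled.chrom_idx == c]
        counts.append(np.bincount(pos // bin_size, minlength=nb)[:nb])
    counts = np.concatenate(counts).astype(np.float64)
    return lorenz_from_counts(counts)


def lorenz_from_counts(counts: np.ndarray) -> LorenzCurve:
    """Lorenz curve and Gini of an arbitrary non-negative count vector."""
    counts = np.sort(np.asarray(counts, dtype=np.float64))
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("no reads in any bin")
    B = counts.shape[0]
    cum_genome = np.concatenate([[0.0], np.arange(1, B + 1) / B])
    cum_reads = np.concatenate([[0.0], np.cumsum(counts) / total])
    area = float(np.trapezoid(cum_reads, cum_genome))
    return LorenzCurve(cum_genome_fraction=cum_genome,
                       cum_read_fraction=cum_reads,
                       gini=1.0 - 2.0 * area)


def filter_cells(qc_list: list[CellQC],
                 umdr_min: int = DEFAULT_UMDR_MIN,
                 mapd_max: float = DEFAULT_MAPD_MAX
                 ) -> tuple[list[CellQC], list[CellQC], dict]:
    """Partition cells into pass/fail on UMDR and MAPD (inclusive bounds).

    Returns (passed, failed, summary); the summary's utilization rate is
    ``None`` for empty input.
    """
    passed, failed = [], []
    for qc in qc_list:
        reasons = []
        if qc.umdr < umdr_min:
            reasons.append("umdr")
        if qc.mapd > mapd_max:
            reasons.append("mapd")
        qc.passed = not reasons
        qc.fail_reason = "+".join(reasons)
        (passed if qc.passed else failed).append(qc)
    summary = {
        "n_total": len(qc_list),
        "n_passed": len(passed),
        "n_failed": len(failed),
        "utilization": len(passed) / len(qc_list) if qc_list else None,
        "umdr_min": umdr_min,
        "mapd_max": mapd_max,
    }
    return passed, failed, summary
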