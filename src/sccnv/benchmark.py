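"""Accuracy benchmarking (sensitivity / FDR vs CNV size) and sequencing
saturation analysis.

The size sweep spikes a fixed number of same-sized CNVs into a synthetic
genome, simulates a low-coverage cell, runs the full calling pipeline and
matches calls against the spiked truth: a call counts as a true positive
when it overlaps at least 50% of a truth segment of the same direction
(gain matched to gain, loss to loss).  Sensitivity is TP/(TP+FN) over the
spiked CNVs; FDR is FP/(FP+TP) over the calls.

The saturation analysis down-samples a cell's unique reads over a fixed
schedule, calls copy number at each depth, and records what fraction of the
bins abnormal at the deepest depth are already abnormal at each shallower
depth.  The fraction is smoothed over log-depth with lowess; the saturation
point is the smallest scheduled depth whose smoothed fraction reaches 99% of
the full-depth value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binning import count_reads, gc_normalize, make_bins
from .errors import InvalidArgumentError
from .genome import GenomeModel
from .segment import call_integer_cn, cbs_segment
from .simulate import (CNVSegment, CloneProfile, NoiseModel, ReadSet,
                       simulate_cell_reads, spike_random_cnvs)

logger = logging.getLogger(__name__)

#: Down-sampling schedule for the saturation analysis (unique reads).
SATURATION_SCHEDULE = (
    30_000, 60_000, 90_000, 120_000, 150_000, 180_000, 210_000, 240_000,
    270_000, 300_000, 450_000, 650_000, 1_050_000, 1_500_000, 2_000_000,
)

DEFAULT_SWEEP_SIZES_MB = (1, 2, 3, 5, 10, 15)
DEFAULT_SWEEP_BINS = (5000, 10_000, 20_000)


@dataclass
class MatchResult:
    """Confusion counts from matching detected CNVs to a simulated truth."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[CNVSegment, CNVSegment]] = field(default_factory=list)


@dataclass
class SaturationCurve:
    """Recovered abnormal-bin fraction per down-sampled depth."""

    depths: np.ndarray
    detected_fraction: np.ndarray
    smoothed_fraction: np.ndarray
    saturation_point: int | None


def _direction(seg: CNVSegment, baseline: int = 2) -> int:
    return 1 if seg.copy_number > baseline else (-1 if seg.copy_number < baseline else 0)


def _overlap(a: CNVSegment, b: CNVSegment) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_cnvs(detected: list[CNVSegment], truth: list[CNVSegment],
               min_overlap: float = 0.5, baseline: int = 2,
               overlap_basis: str = "truth") -> MatchResult:
    """Match detected CNV calls against non-overlapping truth segments.

    A call validates a truth segment when both have the same direction
    (gain/loss relative to ``baseline``) and their overlap is at least
    ``min_overlap`` times the reference length, where ``overlap_basis``
    chooses that reference: the ``"truth"`` segment length (default -- a
    sensitivity-oriented reading), the ``"detected"`` call length, or
    ``"reciprocal"`` (both).  Matching is greedy by descending overlap;
    each truth segment validates at most one call and vice versa.
    """
    if overlap_basis not in ("truth", "detected", "reciprocal"):
        raise InvalidArgumentError(f"unknown overlap_basis {overlap_basis!r}")
    by_chrom: dict[str, list[CNVSegment]] = {}
    for t in truth:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise InvalidArgumentError(
                    f"truth segments overlap on {chrom}: "
                    f"{a.start}-{a.end} / {b.start}-{b.end}")

    candidates = []
    for di, d in enumerate(detected):
        for ti, t in enumerate(truth):
            if _direction(d, baseline) != _direction(t, baseline):
                continue
            ov = _overlap(d, t)
            if ov <= 0:
                continue
            ok_truth = ov >= min_overlap * t.length
            ok_det = ov >= min_overlap * d.length
            ok = {"truth": ok_truth, "detected": ok_det,
                  "reciprocal": ok_truth and ok_det}[overlap_basis]
            if ok:
                candidates.append((ov, di, ti))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for ov, di, ti in candidates:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        pairs.append((detected[di], truth[ti]))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(detected) - tp, fn=len(truth) - tp,
                       matched_pairs=pairs)


def accuracy_metrics(match: MatchResult) -> dict[str, float | None]:
    """Sensitivity TP/(TP+FN) and FDR FP/(FP+TP); None when undefined."""
    sens = match.tp / (match.tp + match.fn) if match.tp + match.fn > 0 else None
    fdr = match.fp / (match.fp + match.tp) if match.fp + match.tp > 0 else None
    return {"sensitivity": sens, "fdr": fdr}


def call_cell(readset: ReadSet, scheme, alpha: float = 0.01,
              nperm: int = 1000, min_width: int = 2, undo_sd: float = 1.0,
              seed: int = 0, span: float = 0.3):
    """Bin -> GC-normalize -> CBS -> integer CN for one cell.

    Returns (BinCounts, RatioProfile, SegmentProfile, CNProfile).
    """
    counts = count_reads(readset, scheme)
    ratios = gc_normalize(counts, scheme, span=span)
    segs = cbs_segment(ratios, alpha=alpha, nperm=nperm, min_width=min_width,
                       undo_sd=undo_sd, seed=seed)
    cn = call_integer_cn(segs)
    return counts, ratios, segs, cn


def run_size_sweep(genome: GenomeModel,
                   sizes_mb: tuple[float, ...] = DEFAULT_SWEEP_SIZES_MB,
                   count: int = 20,
                   replicates: int = 5,
                   n_bins_options: tuple[int, ...] = DEFAULT_SWEEP_BINS,
                   umdr: int = 300_000,
                   noise: NoiseModel | None = None,
                   seed: int = 0,
                   min_overlap: float = 0.5) -> pd.DataFrame:
    """Sensitivity/FDR benchmark over CNV sizes, replicates and bin counts.

    For each (size, replicate): spike ``count`` CNVs, simulate one cell with
    ``umdr`` expected unique reads, then call CNVs under every bin option and
    match against the spiked truth.  Returns a tidy table with one row per
    (size, replicate, n_bins) carrying tp/fp/fn, sensitivity and fdr.
    """
    noise = noise or NoiseModel()
    schemes = {nb: make_bins(genome, nb) for nb in n_bins_options}
    rows = []
    task = 0
    for size_mb in sizes_mb:
        size_bp = int(size_mb * 1_000_000)
        for rep in range(replicates):
            spike_seed = int(np.random.SeedSequence((seed, task, 0)).generate_state(1)[0] % 2**31)
            cell_seed = int(np.random.SeedSequence((seed, task, 1)).generate_state(1)[0] % 2**31)
            task += 1
            profile = spike_random_cnvs(genome, size_bp, count, seed=spike_seed)
            cell_noise = NoiseModel(gc_bias_strength=noise.gc_bias_strength,
                                    dispersion=noise.dispersion,
                                    dup_rate=noise.dup_rate, seed=cell_seed)
            cell = simulate_cell_reads(genome, profile, umdr, cell_noise,
                                       cell_id=f"sweep_{size_mb}Mb_r{rep}")
            for nb in n_bins_options:
                _, _, _, cn = call_cell(cell, schemes[nb], seed=cell_seed + nb)
                match = match_cnvs(cn.calls, profile.segments,
                                   min_overlap=min_overlap)
                metrics = accuracy_metrics(match)
                rows.append({
                    "size_mb": size_mb, "replicate": rep, "n_bins": nb,
                    "tp": match.tp, "fp": match.fp, "fn": match.fn,
                    "sensitivity": metrics["sensitivity"],
                    "fdr": metrics["fdr"],
                })
            logger.info("sweep: size=%s Mb rep=%d done", size_mb, rep)
    return pd.DataFrame(rows)


def sweep_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Median sensitivity and FDR per (size_mb, n_bins) across replicates."""
    return (table.groupby(["size_mb", "n_bins"])[["sensitivity", "fdr"]]
            .median().reset_index())


def saturation_analysis(readset: ReadSet,
                        genome: GenomeModel,
                        schedule: tuple[int, ...] = SATURATION_SCHEDULE,
                        n_bins: int = 5000,
                        seed: int = 0,
                        smooth_frac: float = 0.4,
                        plateau_frac: float = 0.99,
                        alpha: float = 0.01,
                        nperm: int = 1000) -> SaturationCurve:
    """Recovered abnormal-bin fraction as a function of sequencing depth.

    The deepest scheduled depth defines the reference abnormal-bin set; its
    own detected fraction is 1 by construction.  Depths beyond the available
    unique reads are dropped with a warning.  Smoothed fractions are made
    monotone by a running maximum before the plateau rule is applied.
    """
    unique = readset.deduplicated()
    schedule = tuple(sorted(schedule))
    if schedule[-1] > unique.n_raw:
        kept = tuple(d for d in schedule if d <= unique.n_raw)
        warnings.warn(f"only {unique.n_raw} unique reads; truncating schedule "
                      f"to {len(kept)} depths")
        schedule = kept
    if len(schedule) < 2:
        raise InvalidArgumentError("schedule needs >= 2 attainable depths")

    scheme = make_bins(genome, n_bins)
    ss = np.random.SeedSequence(seed)
    depth_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(schedule))]

    masks = []
    for depth, dseed in zip(schedule, depth_seeds):
        sub = unique.subsample_unique(depth, np.random.default_rng(dseed))
        _, _, _, cn = call_cell(sub, scheme, alpha=alpha, nperm=nperm, seed=dseed)
        masks.append(cn.abnormal_bin_mask())

    full = masks[-1]
    n_abnormal = int(full.sum())
    if n_abnormal == 0:
        warnings.warn("no abnormal bins at full depth; saturation undefined")
        return SaturationCurve(depths=np.array(schedule),
                               detected_fraction=np.full(len(schedule), np.nan),
                               smoothed_fraction=np.full(len(schedule), np.nan),
                               saturation_point=None)
    frac = np.array([ (m & full).sum() / n_abnormal for m in masks ])

    logd = np.log10(np.array(schedule, dtype=float))
    smooth = lowess(frac, logd, frac=smooth_frac, it=0, return_sorted=False)
    smooth = np.maximum.accumulate(np.clip(smooth, 0.0, None))
    target = plateau_frac * smooth[-1]
    sat_idx = int(np.argmax(smooth >= target))
    return SaturationCurve(depths=np.array(schedule, dtype=np.int64),
                           detected_fraction=frac,
                           smoothed_fraction=smooth,
                           saturation_point=int(schedule[sat_idx]))
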