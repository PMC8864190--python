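"""End-to-end driver: simulate -> count -> normalize -> QC -> segment ->
call -> cluster -> export, with a checksummed output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binning import count_reads, gc_normalize, make_bins
from .clonal import (clone_consensus, cluster_clones, export_fishplot_table,
                     identify_normal_cells)
from .config import PipelineConfig
from .genome import hg19_scaled_genome
from .io import (write_bins_tsv, write_matrix_tsv, write_profiles_seg,
                 write_segments_seg)
from .presets import (minor_clone_bin_mask, simulate_preset_population,
                      three_clone_preset)
from .qc import CellQC, filter_cells, mapd
from .segment import call_integer_cn, cbs_segment
from .simulate import NoiseModel

logger = logging.getLogger(__name__)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full preset-scenario pipeline and return the output manifest.

    Stages run in order; a failure aborts with the stage named, retaining
    any outputs already written.  Re-running with the same configuration
    reproduces identical checksums.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed, chash = config.seed, config.config_hash()
    manifest: dict = {"version": __version__, "seed": seed,
                      "config_hash": chash, "files": []}

    def record(path: Path, stage: str) -> None:
        manifest["files"].append({"file": path.name, "stage": stage,
                                  "sha256": _checksum(path)})

    stage = "simulate"
    try:
        genome = hg19_scaled_genome(scale=config.genome_scale,
                                    gc_autocorrelation=config.gc_autocorrelation,
                                    seed=seed, window_bp=config.window_bp)
        preset = three_clone_preset(genome)
        if config.cells_scale != 1.0:
            for sample, mix in preset.mixtures.items():
                preset.mixtures[sample] = {
                    clone: int(round(n * config.cells_scale))
                    for clone, n in mix.items()}
        noise = NoiseModel(gc_bias_strength=config.gc_bias_strength,
                           dispersion=config.dispersion,
                           dup_rate=config.dup_rate, seed=seed)
        reads, truth = simulate_preset_population(
            genome, preset, config.n_reads_per_cell, noise, seed=seed,
            samples=config.samples)
        truth_path = outdir / "truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write(f"# seed: {seed}\n# config_hash: {chash}\n")
            truth.to_csv(fh, sep="\t", index=False)
        record(truth_path, stage)
        prof_path = outdir / "clone_profiles.seg.tsv"
        write_profiles_seg(list(preset.clones.values()), prof_path,
                           seed=seed, config_hash=chash)
        record(prof_path, stage)

        stage = "bin"
        scheme = make_bins(genome, config.n_bins)
        bins_path = outdir / "bins.tsv"
        write_bins_tsv(scheme, bins_path, seed=seed, config_hash=chash)
        record(bins_path, stage)

        stage = "qc"
        counts = {rs.cell_id: count_reads(rs, scheme) for rs in reads}
        ratios = {cid: gc_normalize(bc, scheme, span=config.gc_span)
                  for cid, bc in counts.items()}
        qcs = [CellQC(cell_id=cid, n_raw=counts[cid].n_raw,
                      umdr=counts[cid].umdr, dup_rate=counts[cid].dup_rate,
                      mapd=mapd(ratios[cid]))
               for cid in counts]
        passed, failed, summary = filter_cells(qcs, umdr_min=config.umdr_min,
                                               mapd_max=config.mapd_max)
        qc_path = outdir / "qc.tsv"
        with open(qc_path, "w") as fh:
            fh.write(f"# seed: {seed}\n# config_hash: {chash}\n")
            pd.DataFrame([vars(q) for q in qcs]).to_csv(fh, sep="\t", index=False)
        record(qc_path, stage)
        if not passed:
            logger.error("all %d cells failed QC; stopping after QC stage",
                         len(failed))
            manifest["stopped_after"] = "qc"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            return manifest
        keep = [q.cell_id for q in passed]

        stage = "segment"
        ss = np.random.SeedSequence((seed, 1))
        seg_seeds = {cid: int(s.generate_state(1)[0] % 2**31)
                     for cid, s in zip(keep, ss.spawn(len(keep)))}
        segs = {cid: cbs_segment(ratios[cid], alpha=config.alpha,
                                 nperm=config.nperm,
                                 min_width=config.min_width,
                                 undo_sd=config.undo_sd, seed=seg_seeds[cid])
                for cid in keep}
        cns = {cid: call_integer_cn(segs[cid]) for cid in keep}
        seg_rows = []
        for cid in keep:
            sp = segs[cid]
            cn_seg = np.array([cns[cid].cn_per_bin[s]
                               for s in sp.start_bin])
            seg_rows.append((sp, cn_seg))
        seg_path = outdir / "segments.seg.tsv"
        write_segments_seg(seg_rows, seg_path, seed=seed, config_hash=chash)
        record(seg_path, stage)

        stage = "cluster"
        normal = identify_normal_cells(cns)
        tumor_cells = [cid for cid in keep if not normal[cid]]
        ratio_matrix = pd.DataFrame(
            {cid: segs[cid].expand_to_bins() for cid in tumor_cells}).T
        ratio_matrix.columns = scheme.bin_ids()
        mask = minor_clone_bin_mask(scheme) if config.restrict_to_minor_chroms else None
        sample_of = dict(zip(truth["cell_id"], truth["sample"]))
        assignment = cluster_clones(ratio_matrix, k=config.k,
                                    restrict_bins=mask,
                                    sample_labels={c: sample_of[c]
                                                   for c in tumor_cells})
        assign_path = outdir / "assignment.tsv"
        with open(assign_path, "w") as fh:
            fh.write(f"# seed: {seed}\n# config_hash: {chash}\n")
            pd.DataFrame({
                "cell_id": list(assignment.labels),
                "cluster": list(assignment.labels.values()),
                "sample": [assignment.sample_labels[c] for c in assignment.labels],
            }).to_csv(fh, sep="\t", index=False)
        record(assign_path, stage)
        tree_path = outdir / "linkage.tsv"
        with open(tree_path, "w") as fh:
            fh.write(f"# seed: {seed}\n# config_hash: {chash}\n")
            fh.write("node\tleft\tright\theight\n")
            n_leaves = len(assignment.labels)
            for i, (l, r, h, _) in enumerate(assignment.linkage_tree):
                fh.write(f"{n_leaves + i}\t{int(l)}\t{int(r)}\t{h:.6f}\n")
        record(tree_path, stage)

        stage = "export"
        summary_obj = clone_consensus({c: cns[c] for c in tumor_cells}, assignment)
        fish = export_fishplot_table(summary_obj, sample_order=config.samples)
        fish_path = outdir / "fishplot.tsv"
        with open(fish_path, "w") as fh:
            fh.write(f"# seed: {seed}\n# config_hash: {chash}\n")
            fish.to_csv(fh, sep="\t", index=False)
        record(fish_path, stage)
        matrix_path = outdir / "segment_ratios.tsv"
        write_matrix_tsv(ratio_matrix, matrix_path, seed=seed, config_hash=chash)
        record(matrix_path, stage)
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["qc_summary"] = summary
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d files in %s", len(manifest["files"]),
                outdir)
    return manifest
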