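"""Readers and writers for the pipeline's on-disk formats.

All genomic coordinates are 0-based, half-open (BED convention); 1-based
input is not auto-detected.  Files written by the pipeline carry ``#``
header comments recording the master seed and configuration hash so every
output is traceable to the run that produced it.

Formats
-------
reads
    BED: chrom, start, end (= start + read length), cell_id.
clone profiles
    SEG-like TSV: clone, chrom, start, end, cn.
segments / CN calls
    SEG-style TSV: cell_id, chrom, start, end, n_bins, mean_ratio, cn.
matrices
    TSV, cells x bins, header row of bin ids ``chrom:start-end``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import BinScheme
from .errors import FormatError, InvalidArgumentError
from .genome import GenomeModel
from .segment import SegmentProfile
from .simulate import CloneProfile, CNVSegment, ReadSet

DEFAULT_READ_LEN = 100


def _header_lines(seed: int | None, config_hash: str | None) -> str:
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config_hash: {config_hash}")
    return "".join(l + "\n" for l in lines)


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=columns, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {exc}") from exc
    return df


# -- reads (BED) ---------------------------------------------------------

def write_reads_bed(readsets: list[ReadSet], genome: GenomeModel,
                    path: str | Path, read_len: int = DEFAULT_READ_LEN,
                    seed: int | None = None,
                    config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash))
        for rs in readsets:
            names = np.asarray(genome.chrom_names)[rs.chrom_idx]
            block = pd.DataFrame({
                0: names, 1: rs.starts, 2: rs.starts + read_len, 3: rs.cell_id,
            })
            block.to_csv(fh, sep="\t", header=False, index=False)


def read_reads_bed(path: str | Path, genome: GenomeModel,
                   sample_label: str = "sample") -> list[ReadSet]:
    df = _read_table(path, ["chrom", "start", "end", "cell_id"])
    try:
        starts = df["start"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer start coordinate: {exc}") from exc
    chrom_idx = np.array([genome.chrom_index(c) for c in df["chrom"]],
                         dtype=np.int32)
    bad = starts.to_numpy() >= genome.chrom_lengths[chrom_idx]
    if bad.any():
        i = int(np.argmax(bad))
        raise FormatError(
            f"{path} line {i + 1}: start {starts.iloc[i]} beyond "
            f"{df['chrom'].iloc[i]} length")
    out = []
    for cell_id, grp in df.assign(_ci=chrom_idx, _st=starts).groupby(
            "cell_id", sort=True):
        order = np.lexsort((grp["_st"].to_numpy(), grp["_ci"].to_numpy()))
        out.append(ReadSet(cell_id=str(cell_id),
                           chrom_idx=grp["_ci"].to_numpy()[order],
                           starts=grp["_st"].to_numpy()[order],
                           sample_label=sample_label))
    return out


# -- clone profiles (SEG-like) -------------------------------------------

def write_profiles_seg(profiles: list[CloneProfile], path: str | Path,
                       seed: int | None = None,
                       config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash))
        fh.write("clone\tchrom\tstart\tend\tcn\n")
        for prof in profiles:
            for s in prof.segments:
                fh.write(f"{prof.name}\t{s.chrom}\t{s.start}\t{s.end}\t"
                         f"{s.copy_number}\n")


def read_profiles_seg(path: str | Path) -> list[CloneProfile]:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["clone", "chrom", "start", "end", "cn"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, "
                          f"got {list(df.columns)}")
    out = []
    for name, grp in df.groupby("clone", sort=True):
        segs = [CNVSegment(str(r.chrom), int(r.start), int(r.end), int(r.cn))
                for r in grp.itertuples()]
        try:
            out.append(CloneProfile(name=str(name), segments=segs))
        except InvalidArgumentError as exc:
            raise FormatError(f"{path}: clone {name}: {exc}") from exc
    return out


# -- segment profiles ----------------------------------------------------

def write_segments_seg(profiles: list[tuple[SegmentProfile, np.ndarray]],
                       path: str | Path, seed: int | None = None,
                       config_hash: str | None = None) -> None:
    """Write (SegmentProfile, per-segment integer CN) pairs as SEG TSV."""
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash))
        fh.write("cell_id\tchrom\tstart\tend\tn_bins\tmean_ratio\tcn\n")
        for seg, cn_seg in profiles:
            sch = seg.scheme
            for k in range(seg.n_segments):
                s, e = int(seg.start_bin[k]), int(seg.end_bin[k])
                fh.write(f"{seg.cell_id}\t{sch.chrom[s]}\t{sch.start[s]}\t"
                         f"{sch.end[e - 1]}\t{e - s}\t"
                         f"{seg.mean_ratio[k]:.6f}\t{int(cn_seg[k])}\n")


# -- matrices ------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path: str | Path,
                     seed: int | None = None,
                     config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash))
        df.to_csv(fh, sep="\t", index_label="cell_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="cell_id")


# -- bin schemes ---------------------------------------------------------

def write_bins_tsv(scheme: BinScheme, path: str | Path,
                   seed: int | None = None,
                   config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash))
        fh.write("chrom\tstart\tend\tgc\n")
        for c, s, e, g in zip(scheme.chrom, scheme.start, scheme.end, scheme.gc):
            fh.write(f"{c}\t{s}\t{e}\t{g:.6f}\n")


def read_bins_tsv(path: str | Path) -> BinScheme:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["chrom", "start", "end", "gc"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    chrom_names = list(dict.fromkeys(df["chrom"]))
    return BinScheme(chrom=df["chrom"].to_numpy(),
                     start=df["start"].to_numpy(np.int64),
                     end=df["end"].to_numpy(np.int64),
                     gc=df["gc"].to_numpy(float),
                     chrom_names=chrom_names)


# -- config --------------------------------------------------------------

def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a YAML mapping")
    return data


def dump_yaml(data: dict, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_table_tsv(df: pd.DataFrame, path: str | Path,
                    seed: int | None = None,
                    config_hash: str | None = None) -> None:
    """Tidy table with the standard seed/config header comments."""
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash))
        df.to_csv(fh, sep="\t", index=False)
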