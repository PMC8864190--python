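"""Pipeline configuration: one dataclass, YAML round-trip, stable hash."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import InvalidArgumentError
from .io import dump_yaml, load_yaml


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with defaults matching the
    calibrated desk-scale study conditions."""

    # genome
    genome_scale: int = 20            # hg19 lengths divided by this factor
    gc_autocorrelation: float = 0.9
    window_bp: int = 10_000
    # noise
    gc_bias_strength: float = 2.0
    dispersion: float = 0.22
    dup_rate: float = 0.10
    # simulation
    n_reads_per_cell: int = 300_000
    samples: list[str] = field(default_factory=lambda: ["primary", "relapse"])
    cells_scale: float = 1.0          # scale preset cell counts (smoke runs)
    # binning
    n_bins: int = 5000
    target_reads_per_bin: int = 60
    gc_span: float = 0.3
    # segmentation
    alpha: float = 0.01
    nperm: int = 1000
    min_width: int = 2
    undo_sd: float = 1.0
    # QC thresholds
    umdr_min: int = 300_000
    mapd_max: float = 0.45
    # clustering
    k: int = 3
    restrict_to_minor_chroms: bool = True
    # benchmark
    sweep_sizes_mb: list[float] = field(default_factory=lambda: [1, 2, 3, 5, 10, 15])
    sweep_count: int = 20
    sweep_replicates: int = 5
    sweep_bins: list[int] = field(default_factory=lambda: [5000, 10_000, 20_000])
    # run
    seed: int = 0
    outdir: str = "sccnv_out"

    def __post_init__(self) -> None:
        for name in ("n_reads_per_cell", "n_bins", "nperm", "umdr_min",
                     "window_bp", "genome_scale", "k"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.mapd_max < 0:
            raise InvalidArgumentError("mapd_max must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the analysis parameters (output path excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        return hashlib.sha256(dump_yaml(d).encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        dump_yaml(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls(**load_yaml(path))
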