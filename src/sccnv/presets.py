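"""Preset clonal scenarios.

The main preset models a paired primary/relapse liver tumor with three tumor
clones.  All tumor cells share arm-level gains on chromosomes 5, 6p, 7, 8q
and 15q and losses on 6q and 8p.  Two minor clones additionally carry a 1q
gain, a 10q loss and a 14q loss; the later clone (C) carries a higher-level
1q amplification and an extended 10q loss, and expands from a small minority
of the primary tumor to dominate the relapse.  Region coordinates are
expressed as fractions of chromosome length so the preset maps onto any
genome with at least 15 chromosomes, at full or reduced scale.

Default cell mixtures:

=========  =======  =======  =======  ========  ======
sample     clone A  clone B  clone C  normal    total
primary    87       11       5        3         106
relapse    0        12       102      4         118
=========  =======  =======  =======  ========  ======

so the minor clones (B + C) make up 16 of the 103 primary tumor cells
(15.5%) and clone C grows from 5/103 to 102/114 at relapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .genome import GenomeModel
from .simulate import (CloneProfile, CNVSegment, NoiseModel, ReadSet,
                       simulate_population)

# (chrom_index, start_fraction, end_fraction, copy_number) on hg19-proportional
# autosomes; fractions approximate the cytoband extents of the events.
_SHARED_EVENTS = (
    (4, 0.00, 1.00, 3),   # chr5 whole-chromosome gain
    (5, 0.00, 0.38, 3),   # 6p gain (p-ter through q12)
    (5, 0.38, 1.00, 1),   # 6q loss
    (6, 0.00, 1.00, 3),   # chr7 whole-chromosome gain
    (7, 0.00, 0.27, 1),   # 8p loss
    (7, 0.31, 1.00, 3),   # 8q gain
    (14, 0.20, 1.00, 3),  # 15q gain
)

# minor-clone events on the chromosomes that distinguish the relapse lineage
_MINOR_EVENTS_B = (
    (0, 0.578, 1.00, 3),   # 1q gain
    (9, 0.312, 0.680, 1),  # 10q proximal loss
    (13, 0.908, 1.00, 1),  # 14q terminal loss
)
_MINOR_EVENTS_C = (
    (0, 0.578, 1.00, 4),   # higher-level 1q amplification
    (9, 0.312, 0.760, 1),  # extended 10q loss
    (13, 0.908, 1.00, 1),
)

#: chromosome indices carrying minor-clone-specific events (chr1, chr10, chr14)
MINOR_CLONE_CHROMS = (0, 9, 13)

DEFAULT_MIXTURES = {
    "primary": {"A": 87, "B": 11, "C": 5, "normal": 3},
    "relapse": {"A": 0, "B": 12, "C": 102, "normal": 4},
}


@dataclass
class PresetScenario:
    """Clone profiles plus per-sample cell mixtures."""

    clones: dict[str, CloneProfile]
    mixtures: dict[str, dict[str, int]] = field(
        default_factory=lambda: {s: dict(m) for s, m in DEFAULT_MIXTURES.items()})

    def tumor_clones(self) -> list[str]:
        return [name for name in self.clones if name != "normal"]

    def minor_clone_fraction(self, sample: str = "primary") -> float:
        """Fraction of the sample's tumor cells in the minor clones (B u C)."""
        mix = self.mixtures[sample]
        tumor = sum(n for cl, n in mix.items() if cl != "normal")
        return (mix.get("B", 0) + mix.get("C", 0)) / tumor


def _materialize(genome: GenomeModel,
                 events: tuple[tuple[int, float, float, int], ...]) -> list[CNVSegment]:
    segs = []
    for c, f0, f1, cn in events:
        L = int(genome.chrom_lengths[c])
        start, end = int(round(f0 * L)), int(round(f1 * L))
        segs.append(CNVSegment(genome.chrom_names[c], start, end, cn))
    return segs


def three_clone_preset(genome: GenomeModel) -> PresetScenario:
    """Build the paired primary/relapse three-clone tumor scenario.

    Requires a genome with >= 15 chromosomes so the 1q/10q/14q analogue
    regions exist.
    """
    if genome.n_chroms < 15:
        raise InvalidArgumentError(
            "the three-clone preset needs >= 15 chromosomes "
            f"(got {genome.n_chroms})")
    shared = _materialize(genome, _SHARED_EVENTS)
    clone_a = CloneProfile(name="A", segments=list(shared))
    clone_b = CloneProfile(name="B",
                           segments=shared + _materialize(genome, _MINOR_EVENTS_B))
    clone_c = CloneProfile(name="C",
                           segments=shared + _materialize(genome, _MINOR_EVENTS_C))
    normal = CloneProfile(name="normal", segments=[])
    return PresetScenario(clones={"A": clone_a, "B": clone_b, "C": clone_c,
                                  "normal": normal})


def minor_clone_bin_mask(scheme) -> np.ndarray:
    """Boolean mask over a BinScheme's bins selecting the chromosomes that
    carry the minor-clone-specific events (the chr1/10/14 analogues)."""
    names = {f"chr{i + 1}" for i in MINOR_CLONE_CHROMS}
    return np.isin(scheme.chrom, list(names))


def simulate_preset_population(genome: GenomeModel,
                               preset: PresetScenario,
                               n_reads_per_cell: int,
                               noise: NoiseModel,
                               seed: int = 0,
                               samples: list[str] | None = None
                               ) -> tuple[list[ReadSet], pd.DataFrame]:
    """Simulate every sample of a preset scenario.

    Returns one ReadSet per cell and the truth table
    (cell_id, clone, sample).
    """
    if samples is None:
        samples = list(preset.mixtures)
    profiles, counts, labels = [], [], []
    for sample in samples:
        if sample not in preset.mixtures:
            raise InvalidArgumentError(f"unknown sample {sample!r}")
        for clone, n in preset.mixtures[sample].items():
            if n > 0:
                profiles.append(preset.clones[clone])
                counts.append(n)
                labels.append(sample)
    return simulate_population(genome, profiles, counts, n_reads_per_cell,
                               noise, seed=seed, sample_labels=labels)
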