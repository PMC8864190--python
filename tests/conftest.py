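import numpy as np
import pytest

from sccnv import (CloneProfile, NoiseModel, build_genome, hg19_scaled_genome,
                   make_bins)


@pytest.fixture(scope="session")
def small_genome():
    """3 chromosomes x ~16.7 Mb (5000 ten-kb windows total)."""
    return build_genome(3, [16_670_000, 16_670_000, 16_660_000], seed=42)


@pytest.fixture(scope="session")
def small_scheme(small_genome):
    return make_bins(small_genome, 1000)


@pytest.fixture(scope="session")
def scaled_genome():
    """Default desk-scale genome: 22 hg19-proportional autosomes / 20."""
    return hg19_scaled_genome(seed=0)


@pytest.fixture(scope="session")
def scaled_scheme(scaled_genome):
    return make_bins(scaled_genome, 5000)


@pytest.fixture()
def diploid():
    return CloneProfile(name="normal", segments=[])


@pytest.fixture()
def clean_noise():
    """No GC bias, no overdispersion, no duplicates."""
    return NoiseModel(gc_bias_strength=0.0, dispersion=0.0, dup_rate=0.0, seed=1)
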