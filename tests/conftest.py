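import numpy as np
import pytest

from cinpipe.genome import GenomeModel, build_bin_grid


@pytest.fixture
def toy_genome():
    """Two chromosomes: 1 Mb with a centromere at [400k, 600k), and 600 kb
    without a declared centromere."""
    return GenomeModel(
        (("chr1", 1_000_000), ("chr2", 600_000)),
        {"chr1": (400_000, 600_000)},
    )


@pytest.fixture
def toy_grid(toy_genome):
    return build_bin_grid(toy_genome, 200_000)


@pytest.fixture
def mid_genome():
    """Four 160-Mb chromosomes with central centromeres — big enough for
    arm-level events, small enough for replicated end-to-end runs."""
    return GenomeModel(
        tuple((f"chr{i + 1}", 160_000_000) for i in range(4)),
        {f"chr{i + 1}": (75_000_000, 85_000_000) for i in range(4)},
    )


@pytest.fixture
def mid_grid(mid_genome):
    return build_bin_grid(mid_genome, 1_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
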