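import numpy as np
import pytest

from chipqc import (
    GenomeLayout,
    MappedReadSet,
    GradeBoundaries,
    SimulationConfig,
    SubsamplePlan,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def toy_layout():
    """Two small chromosomes, 500 nt bins; chr1 has a truncated last bin."""
    return GenomeLayout((("chr1", 10_000), ("chr2", 5_250)), bin_width=500)


@pytest.fixture(scope="session")
def small_genome():
    """10 Mb single-chromosome genome for fast simulations."""
    return GenomeLayout((("chr1", 10_000_000),), bin_width=500)


@pytest.fixture(scope="session")
def flat_boundaries():
    """Quartile cuts at 25/50/75 for every canonical threshold."""
    return GradeBoundaries(
        {2.5: (25.0, 50.0, 75.0), 5.0: (25.0, 50.0, 75.0), 10.0: (25.0, 50.0, 75.0)},
        "test fixture",
    )


@pytest.fixture(scope="session")
def sharp_reads_200k(small_genome):
    """200k-read sharp-mark dataset on the 10 Mb genome."""
    cfg = SimulationConfig(
        genome=small_genome,
        mark_type="sharp",
        n_regions=500,
        enrichment_fraction=0.6,
        total_reads=200_000,
        seed=11,
    )
    reads, landscape = simulate_dataset(cfg)
    return reads, landscape, cfg


def make_reads(layout, records):
    """Reads from (chrom, start, end[, strand]) tuples."""
    return MappedReadSet.from_records(records, layout)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
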