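import numpy as np
import pytest

from imputebench import GenotypePanel, MarkerMap, SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated population shared by read-only tests."""
    cfg = SimConfig(
        n_haplotypes_founder=150,
        n_samples=60,
        n_markers=300,
        chrom_lengths_bp=(1_000_000, 1_000_000),
        mosaic_generations=250,
        n_haplotypes_pool=1000,
        seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture()
def tiny_panel():
    """Hand-sized panel with a map, for table-level tests."""
    markers = [f"m{i}" for i in range(6)]
    samples = ["s1", "s2", "s3", "s4"]
    geno = np.array(
        [
            [0, 1, 2, 1],
            [0, 0, 0, 0],
            [2, 2, 1, 0],
            [1, 1, 1, 1],
            [0, 2, 0, 2],
            [0, 0, 1, 2],
        ],
        dtype=np.int8,
    )
    panel = GenotypePanel(markers, samples, geno)
    mmap = MarkerMap.from_arrays(
        markers,
        ["1", "1", "1", "2", "2", "2"],
        [1000, 50_000, 120_000, 5_000, 60_000, 99_000],
        "toy",
    )
    return panel, mmap
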