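import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rohsweep.datatypes import GenotypeMatrix, make_marker_map
from rohsweep.simulate import PlantedSegment, SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def three_pop_cohort():
    """A small three-population cohort with planted autozygous segments,
    shared by the slower integration-style tests."""
    cfg = SimConfig(
        pop_names=("A", "B", "C"),
        pop_sizes=(40, 40, 40),
        n_snps=4000,
        n_chroms=2,
        chrom_length_bp=20_000_000,
        target_fst=0.15,
        missing_rate=0.01,
        planted_segments=(
            PlantedSegment("A", 0.4, "1", 5_000_000, 8_000_000),
            PlantedSegment("B", 0.5, "2", 3_000_000, 6_000_000),
        ),
        seed=42,
    )
    g, truth = simulate_genotypes(cfg)
    return cfg, g, truth


def make_matrix(calls, chrom=None, pos=None, populations=None):
    """Convenience constructor for hand-written call matrices."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 10_000
    if chrom is None:
        chrom = ["1"] * m
    if populations is None:
        populations = ["P"] * n
    return GenotypeMatrix(
        calls,
        make_marker_map(chrom, pos),
        [f"s{i}" for i in range(n)],
        list(populations),
    )


@pytest.fixture
def make_g():
    return make_matrix
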