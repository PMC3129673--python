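import numpy as np
import pandas as pd
import pytest

from clusterscape.genome import Gene, GenomeMap
from clusterscape.simulate import SimulationConfig, simulate_all


def make_genome(spec):
    """Build a GenomeMap from (id, arm, start, end, strand) tuples."""
    return GenomeMap([Gene(*row) for row in spec])


@pytest.fixture
def toy_genome():
    """Three well-separated genes on one arm plus two on another."""
    return make_genome(
        [
            ("a1", "2L", 1, 100, "+"),
            ("a2", "2L", 201, 300, "-"),
            ("a3", "2L", 401, 500, "+"),
            ("b1", "2R", 1, 150, "-"),
            ("b2", "2R", 301, 400, "+"),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_arms=3,
        genes_per_arm=400,
        n_type1=12,
        n_hk_runs=6,
        n_inversions_focal=15,
        n_inversions_outgroup=15,
        n_translocations_focal=1,
        n_translocations_outgroup=1,
        n_duplicate_pairs=20,
    )
    return simulate_all(cfg, seed=20_240_601)


def spaced_genome(n, arm="2L", seed=None, gene_len=100, igd=50, prefix="g"):
    """Regular non-overlapping single-arm genome of n genes."""
    rng = np.random.default_rng(seed)
    genes = []
    pos = 1
    for i in range(n):
        strand = "+" if (rng.random() < 0.5 if seed is not None else i % 2 == 0) else "-"
        genes.append(Gene(f"{prefix}{i:04d}", arm, pos, pos + gene_len - 1, strand))
        pos += gene_len + igd
    return GenomeMap(genes)
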