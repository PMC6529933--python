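import numpy as np
import pytest

from tucall.core import CoverageTrack, GeneAnnotation, Genome
from tucall.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clear_sim():
    """A small clear-regime dataset shared by read-only tests."""
    config = SimConfig.clear_regime(n_genes=80)
    genome, genes, truth, coverage = simulate_dataset(config, seed=11)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "coverage": coverage,
    }


@pytest.fixture
def flat_genome():
    """One 2 kb replicon with three + strand genes under uniform depth 10."""
    genome = Genome(lengths={"chrA": 2000})
    genes = [
        GeneAnnotation("gA", "chrA", 100, 700, "+"),
        GeneAnnotation("gB", "chrA", 750, 1350, "+"),
        GeneAnnotation("gC", "chrA", 1400, 1900, "+"),
    ]
    coverage = CoverageTrack({"chrA": np.full(2000, 10.0)})
    return genome, genes, coverage


def random_pair_region(rng, allow_empty_intergenic=True):
    """A synthetic GenePairRegion with random slices, for oracle tests."""
    from tucall.core import GenePairRegion

    n_up = int(rng.integers(1, 400))
    n_down = int(rng.integers(1, 400))
    n_ig = int(rng.integers(0 if allow_empty_intergenic else 1, 200))
    total = n_up + n_ig + n_down
    depth = rng.choice(
        [0.0, 0.0, 1.0, 3.0, 10.0, 50.0], size=total, p=[0.2, 0.1, 0.2, 0.2, 0.2, 0.1]
    )
    up = GeneAnnotation("u", "chr", 10, 10 + n_up, "+")
    down = GeneAnnotation("d", "chr", 10 + n_up + n_ig, 10 + total, "+")
    pair = GenePairRegion(
        up_gene=up,
        down_gene=down,
        replicon="chr",
        strand="+",
        intergenic_start=up.end,
        intergenic_end=down.start,
        up_cov=depth[:n_up],
        intergenic_cov=depth[n_up : n_up + n_ig],
        down_cov=depth[n_up + n_ig :],
    )
    return pair
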