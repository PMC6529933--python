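"""Constructed-TU training set: splitting geometry, negatives, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from tucall.core import CoverageTrack, GeneAnnotation, Genome
from tucall.features import gap_proportion
from tucall.simulate import SimConfig, simulate_dataset
from tucall.trainset import (
    TrainConfig,
    build_training_set,
    construct_negative_pair,
    construct_positive_pair,
    find_silent_regions,
    select_splittable_genes,
)


def _uniform_case(depth=10.0, n=3000):
    genome = Genome(lengths={"chrA": n})
    coverage = CoverageTrack({"chrA": np.full(n, depth)})
    return genome, coverage


class TestSelectSplittable:
    def test_threshold_filters(self):
        _, cov = _uniform_case(10.0)
        short = GeneAnnotation("s", "chrA", 0, 300, "+")
        ok = GeneAnnotation("g", "chrA", 400, 1300, "+")
        got = select_splittable_genes([short, ok], cov, min_len=600, min_mean_depth=5)
        assert got == [ok]

    def test_empty_result_is_error(self):
        _, cov = _uniform_case(0.0)
        g = GeneAnnotation("g", "chrA", 0, 900, "+")
        with pytest.raises(ValueError, match="splittable"):
            select_splittable_genes([g], cov)

    def test_matches_bruteforce_filter(self, clear_sim):
        """Selection equals an independent per-gene re-filter."""
        genes, cov = clear_sim["genes"], clear_sim["coverage"]
        got = select_splittable_genes(genes, cov, 600, 5.0, 0.1)
        want = []
        for g in genes:  # naive re-check
            d = cov[g.replicon][g.start:g.end]
            if (
                g.length >= 600
                and d.mean() >= 5.0
                and (d <= 0).mean() <= 0.1
            ):
                want.append(g)
        assert got == want


class TestPositivePair:
    def test_centered_split_arithmetic(self):
        _, cov = _uniform_case()
        g = GeneAnnotation("g", "chrA", 0, 900, "+")  # spans 1..900 1-based
        pair = construct_positive_pair(g, cov, 100)
        assert (pair.up_gene.start, pair.up_gene.end) == (0, 400)
        assert (pair.intergenic_start, pair.intergenic_end) == (400, 500)
        assert (pair.down_gene.start, pair.down_gene.end) == (500, 900)

    def test_zero_pseudo_len_abuts(self):
        _, cov = _uniform_case()
        g = GeneAnnotation("g", "chrA", 0, 900, "+")
        pair = construct_positive_pair(g, cov, 0)
        assert pair.intergenic_length == 0
        assert pair.up_gene.end == pair.down_gene.start

    def test_parts_tile_gene_exactly(self):
        """Property: the three parts are disjoint, contiguous, and cover the gene."""
        rng = np.random.default_rng(0)
        _, cov = _uniform_case(n=20000)
        for _ in range(200):
            length = int(rng.integers(600, 3000))
            p = int(rng.integers(0, length // 3 + 1))
            g = GeneAnnotation("g", "chrA", 100, 100 + length, "+")
            try:
                pair = construct_positive_pair(g, cov, p)
            except ValueError:
                assert min((length - p) // 2, length - p - (length - p) // 2) < 150
                continue
            assert pair.up_gene.end == pair.intergenic_start
            assert pair.intergenic_end == pair.down_gene.start
            assert pair.up_gene.start == g.start and pair.down_gene.end == g.end
            total = pair.up_gene.length + pair.intergenic_length + pair.down_gene.length
            assert total == length

    def test_pseudo_len_cap_enforced(self):
        _, cov = _uniform_case()
        g = GeneAnnotation("g", "chrA", 0, 900, "+")
        with pytest.raises(ValueError):
            construct_positive_pair(g, cov, 301)

    def test_minus_strand_orientation(self):
        n = 2000
        genome = Genome(lengths={"chrA": n})
        depth = np.arange(n, dtype=float)  # ramp marks genomic position
        cov = CoverageTrack({"chrA": depth})
        g = GeneAnnotation("g", "chrA", 100, 1000, "-")
        pair = construct_positive_pair(g, cov, 90)
        # 5' end of a minus-strand gene is its highest genomic coordinate
        assert pair.up_cov[0] == 999.0
        assert pair.down_cov[-1] == 100.0


class TestNegativePair:
    def test_break_with_silent_donor(self):
        genome = Genome(lengths={"chrA": 4000})
        depth = np.zeros(4000)
        depth[:1000] = 10.0
        cov = CoverageTrack({"chrA": depth})
        g = GeneAnnotation("g", "chrA", 0, 900, "+")
        pool = [("chrA", 2000, 3500)]
        rng = np.random.default_rng(0)
        pair = construct_negative_pair(g, pool, cov, 100, rng)
        assert gap_proportion(pair.intergenic_cov) == 1.0
        assert gap_proportion(pair.down_cov) == 1.0
        assert pair.up_cov.mean() == 10.0

    def test_sparse_donor_gap_proportion(self):
        """A 10%-covered donor leaves ~90% gap bases in the sampled slice."""
        rng = np.random.default_rng(1)
        depth = np.zeros(6000)
        depth[:1000] = 10.0
        mask = rng.random(4000) < 0.1
        depth[2000:6000][mask] = 1.0
        cov = CoverageTrack({"chrA": depth})
        g = GeneAnnotation("g", "chrA", 0, 900, "+")
        pair = construct_negative_pair(g, [("chrA", 2000, 6000)], cov, 100, rng)
        joint = np.concatenate([pair.intergenic_cov, pair.down_cov])
        assert gap_proportion(joint) == pytest.approx(0.9, abs=0.06)

    def test_empty_pool_is_error(self):
        _, cov = _uniform_case()
        g = GeneAnnotation("g", "chrA", 0, 900, "+")
        with pytest.raises(ValueError, match="opposite_strand"):
            construct_negative_pair(g, [], cov, 100, np.random.default_rng(0))


@pytest.fixture(scope="module")
def sim():
    return simulate_dataset(SimConfig.clear_regime(n_genes=120), seed=3)


class TestBuildTrainingSet:
    def _config(self):
        return TrainConfig(min_splittable=10)

    def test_deterministic_given_seed(self, sim):
        _, genes, _, cov = sim
        a = build_training_set(genes, cov, self._config(), seed=5)
        b = build_training_set(genes, cov, self._config(), seed=5)
        pd.testing.assert_frame_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_invariant_to_gene_order(self, sim):
        _, genes, _, cov = sim
        a = build_training_set(genes, cov, self._config(), seed=5)
        shuffled = list(genes)
        np.random.default_rng(0).shuffle(shuffled)
        b = build_training_set(shuffled, cov, self._config(), seed=5)
        pd.testing.assert_frame_equal(a.X, b.X)

    def test_balanced_and_capped(self, sim):
        _, genes, _, cov = sim
        ts = build_training_set(genes, cov, TrainConfig(min_splittable=10, class_cap=30), seed=1)
        assert (ts.y == 1).sum() == (ts.y == 0).sum() <= 30

    def test_no_nan_across_seeds(self, sim):
        _, genes, _, cov = sim
        for seed in range(10):
            ts = build_training_set(genes, cov, self._config(), seed=seed)
            assert np.isfinite(ts.X.to_numpy()).all()

    def test_class_geometries_indistinguishable(self, sim):
        """Positive vs negative total region lengths: same distribution (KS)."""
        _, genes, _, cov = sim
        ts = build_training_set(genes, cov, self._config(), seed=7)
        lens = ts.provenance["pseudo_intergenic_len"].to_numpy(float)
        pos, neg = lens[ts.y == 1], lens[ts.y == 0]
        assert ks_2samp(pos, neg).pvalue > 0.01

    def test_gap_feature_separates_classes(self, sim):
        """Clear regime: gap proportion alone splits the classes linearly."""
        _, genes, _, cov = sim
        ts = build_training_set(genes, cov, self._config(), seed=2)
        gp = ts.X["gap_prop_intergenic"].to_numpy()
        assert gp[ts.y == 1].max() < 0.5 <= gp[ts.y == 0].min()

    def test_opposite_strand_mode(self, sim):
        _, genes, _, cov = sim
        config = TrainConfig(min_splittable=10, negatives_mode="opposite_strand")
        ts = build_training_set(genes, cov, config, seed=4)
        assert (ts.y == 0).sum() > 0


def test_silent_regions_are_below_threshold(clear_sim):
    genes, cov = clear_sim["genes"], clear_sim["coverage"]
    for rep, s, e in find_silent_regions(genes, cov, silent_threshold=1.0):
        assert cov.slice(rep, s, e).mean() < 1.0
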