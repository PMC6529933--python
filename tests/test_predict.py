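"""Candidate enumeration, classification, TU concatenation and summaries."""

import numpy as np
import pytest

from tucall.core import ClassifiedPair, GeneAnnotation, GenePairRegion, TUCall
from tucall.model import ModelConfig, fit
from tucall.predict import (
    classify_pairs,
    concatenate_tus,
    enumerate_candidate_pairs,
    pairwise_f1,
    tu_size_summary,
)
from tucall.simulate import SimConfig, simulate_annotation, simulate_dataset
from tucall.trainset import TrainConfig, build_training_set


def genes_from_layout(layout):
    """layout: list of (id, strand) laid out left-to-right without overlap."""
    out, pos = [], 100
    for gid, strand in layout:
        out.append(GeneAnnotation(gid, "chrA", pos, pos + 300, strand))
        pos += 400
    return out


def _positive(a, b):
    strand = a.strand
    up, down = (a, b) if strand == "+" else (b, a)
    pair = GenePairRegion(up_gene=up, down_gene=down, replicon=a.replicon,
                          strand=strand, intergenic_start=a.end,
                          intergenic_end=max(b.start, a.end))
    return ClassifiedPair(pair=pair, features={}, probability=0.99, co_transcribed=True)


class TestEnumerate:
    def test_same_strand_run(self):
        genes = genes_from_layout([("A", "+"), ("B", "+"), ("C", "+")])
        cands, forced = enumerate_candidate_pairs(genes)
        assert [(p.up_gene.gene_id, p.down_gene.gene_id) for p in cands] == [
            ("A", "B"), ("B", "C")]
        assert forced == []

    def test_opposite_strand_interruption(self):
        genes = genes_from_layout([("A", "+"), ("B", "-"), ("C", "+")])
        cands, forced = enumerate_candidate_pairs(genes)
        assert cands == []
        assert [(a.gene_id, b.gene_id, r) for a, b, r in forced] == [
            ("A", "C", "intervening gene")]

    def test_minus_pair_orientation(self):
        genes = genes_from_layout([("A", "-"), ("B", "-")])
        cands, _ = enumerate_candidate_pairs(genes)
        # upstream (5') gene of a minus pair is the higher-coordinate one
        assert (cands[0].up_gene.gene_id, cands[0].down_gene.gene_id) == ("B", "A")

    def test_overlapping_genes_empty_intergenic(self):
        genes = [GeneAnnotation("A", "chrA", 100, 500, "+"),
                 GeneAnnotation("B", "chrA", 450, 900, "+")]
        cands, _ = enumerate_candidate_pairs(genes)
        assert len(cands) == 1 and cands[0].intergenic_length == 0

    def test_matches_quadratic_oracle(self):
        """Candidate set equals an O(n²) scan applying the adjacency rule."""
        rng = np.random.default_rng(4)
        for trial in range(10):
            _, genes, _ = simulate_annotation(SimConfig(n_genes=40), seed=trial)
            cands, _ = enumerate_candidate_pairs(genes)
            got = {(p.up_gene.gene_id, p.down_gene.gene_id) for p in cands}
            want = set()
            for a in genes:  # brute force over all ordered pairs
                for b in genes:
                    if a is b or a.replicon != b.replicon or a.strand != b.strand:
                        continue
                    if a.start >= b.start:
                        continue
                    between = [c for c in genes
                               if c is not a and c is not b
                               and c.replicon == a.replicon
                               and a.start < c.start < b.start]
                    if between:
                        continue
                    up, down = (a, b) if a.strand == "+" else (b, a)
                    want.add((up.gene_id, down.gene_id))
            assert got == want


class TestConcatenate:
    def test_chain_and_singleton(self):
        genes = genes_from_layout([("A", "+"), ("B", "+"), ("C", "+"), ("D", "+")])
        pairs = [_positive(genes[0], genes[1]), _positive(genes[1], genes[2])]
        tus = concatenate_tus(genes, pairs)
        assert [t.gene_ids for t in tus] == [["A", "B", "C"], ["D"]]
        assert tus[0].start == 100 and tus[0].end == 100 + 2 * 400 + 300

    def test_no_positives_all_singletons(self):
        genes = genes_from_layout([("A", "+"), ("B", "-"), ("C", "+")])
        tus = concatenate_tus(genes, [])
        assert all(t.n_genes == 1 for t in tus) and len(tus) == 3

    def test_non_candidate_positive_is_error(self):
        genes = genes_from_layout([("A", "+"), ("B", "-"), ("C", "+")])
        with pytest.raises(ValueError, match="not a candidate"):
            concatenate_tus(genes, [_positive(genes[0], genes[2])])

    def test_counting_identity_and_partition(self):
        """#TUs = #genes − #positive pairs; members partition the gene set."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            _, genes, _ = simulate_annotation(SimConfig(n_genes=50), seed=100 + trial)
            cands, _ = enumerate_candidate_pairs(genes)
            chosen = [p for p in cands if rng.random() < 0.5]
            pairs = [_positive(*sorted((p.up_gene, p.down_gene), key=lambda g: g.start))
                     for p in chosen]
            tus = concatenate_tus(genes, pairs)
            assert len(tus) == len(genes) - len(chosen)
            members = [g for t in tus for g in t.gene_ids]
            assert sorted(members) == sorted(g.gene_id for g in genes)

    def test_minus_strand_tu_listed_5prime_first(self):
        genes = genes_from_layout([("A", "-"), ("B", "-")])
        tus = concatenate_tus(genes, [_positive(genes[0], genes[1])])
        assert tus[0].gene_ids == ["B", "A"]


@pytest.fixture(scope="module")
def trained():
    config = SimConfig.clear_regime(n_genes=120)
    _, genes, truth, cov = simulate_dataset(config, seed=21)
    ts = build_training_set(genes, cov, TrainConfig(min_splittable=10), seed=21)
    bundle = fit(ts.X, ts.y, ModelConfig(), seed=21)
    return genes, truth, cov, bundle


class TestClassify:
    def test_planted_positive_and_negative(self, trained):
        genes, truth, cov, bundle = trained
        cands, forced = enumerate_candidate_pairs(genes)
        classified = classify_pairs(bundle, cands, cov, forced)
        labels = truth.true_pair_labels(genes)
        by_key = {frozenset((c.up_id, c.down_id)): c for c in classified}
        n_correct = sum(
            by_key[k].co_transcribed == v for k, v in labels.items() if k in by_key
        )
        assert n_correct / len(labels) >= 0.95
        # within-TU pairs score high, cross-TU pairs low, on average
        pos = [by_key[k].probability for k, v in labels.items() if v and k in by_key]
        neg = [by_key[k].probability for k, v in labels.items() if not v and k in by_key]
        assert np.mean(pos) > 0.9 > 0.1 > np.mean(neg)

    def test_repeat_classification_identical(self, trained):
        genes, _, cov, bundle = trained
        cands, _ = enumerate_candidate_pairs(genes)
        a = classify_pairs(bundle, cands[:5], cov)
        b = classify_pairs(bundle, cands[:5], cov)
        assert [c.probability for c in a] == [c.probability for c in b]

    def test_missing_replicon_is_error(self, trained):
        genes, _, cov, bundle = trained
        ghost = [GeneAnnotation("x1", "ghost", 0, 900, "+"),
                 GeneAnnotation("x2", "ghost", 1000, 1900, "+")]
        cands, _ = enumerate_candidate_pairs(ghost)
        with pytest.raises(KeyError, match="ghost"):
            classify_pairs(bundle, cands, cov)

    def test_forced_negatives_carry_reason(self, trained):
        genes, _, cov, bundle = trained
        _, forced = enumerate_candidate_pairs(genes)
        if not forced:
            pytest.skip("no forced negatives in this layout")
        classified = classify_pairs(bundle, [], cov, forced)
        assert all(c.reason == "intervening gene" and not c.co_transcribed
                   for c in classified)


class TestSummary:
    def test_categories(self):
        def tu(n):
            return TUCall("t", "chrA", "+", [f"g{i}" for i in range(n)], 0, 100)

        s = tu_size_summary([tu(1), tu(1), tu(2), tu(3)])
        assert s == {"single_gene": 2, "two_gene": 1, "multi_gene": 1, "total": 4}

    def test_empty(self):
        s = tu_size_summary([])
        assert s == {"single_gene": 0, "two_gene": 0, "multi_gene": 0, "total": 0}

    def test_simulated_run_matches_tally(self, clear_sim):
        genes = clear_sim["genes"]
        tus = concatenate_tus(genes, [])
        s = tu_size_summary(tus)
        assert s["total"] == len(genes)
        assert s["single_gene"] + s["two_gene"] + s["multi_gene"] == s["total"]


def test_pairwise_f1_definition():
    a, b, c = frozenset("ab"), frozenset("bc"), frozenset("cd")
    out = pairwise_f1({a, b}, {b, c})
    assert out["precision"] == 0.5 and out["recall"] == 0.5 and out["f1"] == 0.5
    assert pairwise_f1({a}, {a})["f1"] == 1.0
    assert pairwise_f1(set(), {a})["f1"] == 0.0
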