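"""Labeled training data from "constructed TUs".

Real operon/TU membership labels are unknown at training time, so the
training set is manufactured from the data itself: a well-expressed
single gene is split into two sub-genes and a pseudo-intergenic window.
Because depth inside a gene is continuous and stable, such a pair looks
exactly like a co-transcribed pair whose intergenic region is
transcribed — a positive example with real noise characteristics.

Negative examples (a coverage break between the genes) come in two
constructed flavours, mixed half and half so the break topology — not
any single flank — carries the label:

* *full break*: keep the 5' sub-gene of an expressed gene and splice
  both the intergenic window and the downstream sub-gene from a
  *silent* donor region (transcription stops after the first gene);
* *intergenic break*: the same centered split as a positive, real
  coverage on both sub-genes, but the intergenic window alone replaced
  by silent-donor depth (two expressed units separated by a quiet gap —
  the usual appearance of a genuine TU boundary).

Part lengths are drawn exactly as for positives, so the classes cannot
be told apart by geometry alone.  An alternative mode uses real
adjacent opposite-strand gene pairs as negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageTrack, GeneAnnotation, GenePairRegion
from .features import FEATURE_NAMES, extract_features, gap_proportion

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainingSet",
    "select_splittable_genes",
    "construct_positive_pair",
    "construct_negative_pair",
    "construct_intergenic_break_pair",
    "find_silent_regions",
    "build_training_set",
]


@dataclass(frozen=True)
class TrainConfig:
    """Thresholds for constructed-TU training-set generation.

    Defaults target a typical bacterial genome: genes of ≥600 bp can be
    split into two ≥150 bp sub-genes plus a pseudo-intergenic window,
    mean depth ≥5 with ≤10% gap bases marks a gene as confidently
    expressed, and mean depth <1 marks a region as silent enough to act
    as a negative donor.
    """

    min_gene_len: int = 600
    min_mean_depth: float = 5.0
    max_gap_prop: float = 0.1
    min_subgene_len: int = 150
    silent_threshold: float = 1.0
    class_cap: int = 2000
    min_splittable: int = 20
    gap_threshold: float = 0.0
    negatives_mode: str = "silent_donor"  # or "opposite_strand"


@dataclass
class TrainingSet:
    """Feature matrix, labels and per-row provenance."""

    X: pd.DataFrame  # columns = FEATURE_NAMES
    y: np.ndarray  # 1 = co-transcribed (positive), 0 = not
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.isna().any().any() or not np.isfinite(self.X.to_numpy()).all():
            raise ValueError("training features contain NaN/Inf")
        if len(set(self.y)) < 2:
            raise ValueError("training set must contain both classes")


def select_splittable_genes(
    genes: list[GeneAnnotation],
    coverage: CoverageTrack,
    min_len: int = 600,
    min_mean_depth: float = 5.0,
    max_gap_prop: float = 0.1,
    gap_threshold: float = 0.0,
) -> list[GeneAnnotation]:
    """Genes long and well-expressed enough to be split into a constructed pair."""
    out = []
    for g in genes:
        if g.length < min_len:
            continue
        depths = coverage.slice(g.replicon, g.start, g.end)
        if np.mean(depths) < min_mean_depth:
            continue
        if gap_proportion(depths, gap_threshold) > max_gap_prop:
            continue
        out.append(g)
    if not out:
        raise ValueError(
            "no splittable genes found; lower min_len/min_mean_depth or raise "
            "max_gap_prop (training is impossible without them)"
        )
    return out


def _split_lengths(gene_len: int, pseudo_len: int, min_subgene_len: int) -> tuple[int, int, int]:
    if pseudo_len < 0 or pseudo_len > gene_len // 3:
        raise ValueError(
            f"pseudo-intergenic length {pseudo_len} must be in [0, gene_len//3 = {gene_len // 3}]"
        )
    len1 = (gene_len - pseudo_len) // 2
    len2 = gene_len - pseudo_len - len1
    if min(len1, len2) < min_subgene_len:
        raise ValueError(
            f"sub-gene lengths ({len1}, {len2}) below minimum {min_subgene_len}"
        )
    return len1, pseudo_len, len2


def _pseudo_gene(src: GeneAnnotation, tag: str, start: int, end: int) -> GeneAnnotation:
    return GeneAnnotation(
        gene_id=f"{src.gene_id}::{tag}",
        replicon=src.replicon,
        start=start,
        end=end,
        strand=src.strand,
        locus_tag=src.locus_tag,
    )


def construct_positive_pair(
    gene: GeneAnnotation,
    coverage: CoverageTrack,
    pseudo_intergenic_len: int,
    min_subgene_len: int = 150,
) -> GenePairRegion:
    """Split one expressed gene into a positive constructed pair.

    The gene's interval is partitioned into sub-gene-1, a *centered*
    pseudo-intergenic window, and sub-gene-2; all three keep the real
    observed coverage (intragenic depth plays the transcribed-intergenic
    role).  The three parts tile the gene exactly.
    """
    len1, p, len2 = _split_lengths(gene.length, pseudo_intergenic_len, min_subgene_len)
    a, b = gene.start + len1, gene.start + len1 + p
    left = _pseudo_gene(gene, "5p" if gene.strand == "+" else "3p", gene.start, a)
    right = _pseudo_gene(gene, "3p" if gene.strand == "+" else "5p", b, gene.end)
    up, down = (left, right) if gene.strand == "+" else (right, left)
    pair = GenePairRegion(
        up_gene=up,
        down_gene=down,
        replicon=gene.replicon,
        strand=gene.strand,
        intergenic_start=a,
        intergenic_end=b,
        source="constructed_positive",
    )
    return pair.attach_coverage(coverage)


def find_silent_regions(
    genes: list[GeneAnnotation],
    coverage: CoverageTrack,
    silent_threshold: float = 1.0,
    min_len: int = 30,
) -> list[tuple[str, int, int]]:
    """Donor regions for negatives: intergenic intervals and silent genes.

    A region qualifies when its mean depth is below ``silent_threshold``.
    """
    regions: list[tuple[str, int, int]] = []
    by_rep: dict[str, list[GeneAnnotation]] = {}
    for g in sorted(genes, key=lambda g: (g.replicon, g.start)):
        by_rep.setdefault(g.replicon, []).append(g)

    for rep, gs in by_rep.items():
        n = coverage[rep].size
        cursor = 0
        for g in gs:
            if g.start - cursor >= min_len:
                regions.append((rep, cursor, g.start))
            cursor = max(cursor, g.end)
        if n - cursor >= min_len:
            regions.append((rep, cursor, n))
        for g in gs:
            if g.length >= min_len:
                regions.append((rep, g.start, g.end))

    return [
        (rep, s, e)
        for rep, s, e in regions
        if np.mean(coverage.slice(rep, s, e)) < silent_threshold
    ]


def _donor_slice(
    pool: list[tuple[str, int, int]],
    coverage: CoverageTrack,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    rep, s, e = pool[rng.integers(len(pool))]
    donor = coverage.slice(rep, s, e)
    if donor.size >= length:
        off = int(rng.integers(donor.size - length + 1))
        return donor[off : off + length].copy()
    return np.resize(donor, length)  # tile short donors


def construct_negative_pair(
    expressed_gene: GeneAnnotation,
    silent_pool: list[tuple[str, int, int]],
    coverage: CoverageTrack,
    pseudo_intergenic_len: int,
    rng: np.random.Generator,
    min_subgene_len: int = 150,
) -> GenePairRegion:
    """Build a negative constructed pair showing a coverage break.

    Sub-gene-1 keeps the 5' half of a real expressed gene; the
    pseudo-intergenic window and sub-gene-2 take depth from a sampled
    silent donor region.  Part lengths follow the same split arithmetic
    as a positive draw so length alone cannot separate the classes.
    """
    if not silent_pool:
        raise ValueError(
            "silent donor pool is empty; raise silent_threshold or use "
            "negatives_mode='opposite_strand'"
        )
    len1, p, len2 = _split_lengths(
        expressed_gene.length, pseudo_intergenic_len, min_subgene_len
    )
    g = expressed_gene
    # genomic-orientation positions of the 5' part
    if g.strand == "+":
        a, b = g.start + len1, g.start + len1 + p
        left = _pseudo_gene(g, "5p", g.start, a)
        right = _pseudo_gene(g, "3p", b, g.end)
        up, down = left, right
    else:
        a, b = g.end - len1 - p, g.end - len1
        left = _pseudo_gene(g, "3p", g.start, a)
        right = _pseudo_gene(g, "5p", b, g.end)
        up, down = right, left
    pair = GenePairRegion(
        up_gene=up,
        down_gene=down,
        replicon=g.replicon,
        strand=g.strand,
        intergenic_start=a,
        intergenic_end=b,
        source="constructed_negative",
    )
    pair.attach_coverage(coverage)
    # replace intergenic + downstream depth with silent-donor depth
    donor = _donor_slice(silent_pool, coverage, p + len2, rng)
    pair.intergenic_cov = donor[:p]
    pair.down_cov = donor[p:]
    return pair


def construct_intergenic_break_pair(
    expressed_gene: GeneAnnotation,
    silent_pool: list[tuple[str, int, int]],
    coverage: CoverageTrack,
    pseudo_intergenic_len: int,
    rng: np.random.Generator,
    min_subgene_len: int = 150,
) -> GenePairRegion:
    """Negative with the break confined to the intergenic window.

    Both sub-genes keep the expressed gene's real coverage (same
    centered split as a positive); only the pseudo-intergenic window is
    replaced with silent-donor depth.  This is how a genuine TU boundary
    between two expressed TUs looks, and it forces the classifier to
    read the break itself rather than a silent downstream flank.
    Requires a non-empty window (use the full-break construction when
    the pseudo-intergenic length is 0).
    """
    if pseudo_intergenic_len <= 0:
        raise ValueError("intergenic-break negative needs a non-empty window")
    if not silent_pool:
        raise ValueError(
            "silent donor pool is empty; raise silent_threshold or use "
            "negatives_mode='opposite_strand'"
        )
    pair = construct_positive_pair(
        expressed_gene, coverage, pseudo_intergenic_len, min_subgene_len
    )
    pair.source = "constructed_negative"
    pair.intergenic_cov = _donor_slice(
        silent_pool, coverage, pseudo_intergenic_len, rng
    )
    return pair


def _empirical_intergenic_lengths(genes: list[GeneAnnotation]) -> np.ndarray:
    """Distances between same-strand adjacent genes (the real intergenic sizes)."""
    dists = []
    ordered = sorted(genes, key=lambda g: (g.replicon, g.start))
    for a, b in zip(ordered[:-1], ordered[1:]):
        if a.replicon == b.replicon and a.strand == b.strand:
            dists.append(max(b.start - a.end, 0))
    return np.asarray(dists, dtype=np.int64)


def _opposite_strand_pairs(
    genes: list[GeneAnnotation], coverage: CoverageTrack
) -> list[GenePairRegion]:
    ordered = sorted(genes, key=lambda g: (g.replicon, g.start))
    out = []
    for a, b in zip(ordered[:-1], ordered[1:]):
        if a.replicon != b.replicon or a.strand == b.strand:
            continue
        if b.start <= a.end:  # overlapping; no clean break to learn from
            continue
        pair = GenePairRegion(
            up_gene=a,
            down_gene=b,
            replicon=a.replicon,
            strand=a.strand,
            intergenic_start=a.end,
            intergenic_end=b.start,
            source="constructed_negative",
        )
        out.append(pair.attach_coverage(coverage))
    return out


def build_training_set(
    genes: list[GeneAnnotation],
    coverage: CoverageTrack,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> TrainingSet:
    """Assemble the balanced constructed-TU training set.

    Pseudo-intergenic lengths are drawn from the empirical distribution
    of real same-strand adjacent intergenic distances, truncated per gene
    to what its length allows.  One constructed pair per splittable gene;
    classes balanced 1:1 by downsampling, capped at ``class_cap``.
    Deterministic given ``seed`` and invariant to gene input order.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(genes, key=lambda g: (g.replicon, g.start, g.gene_id))

    splittable = select_splittable_genes(
        genes,
        coverage,
        config.min_gene_len,
        config.min_mean_depth,
        config.max_gap_prop,
        config.gap_threshold,
    )
    if len(splittable) < config.min_splittable:
        raise ValueError(
            f"only {len(splittable)} splittable genes (< {config.min_splittable}); "
            "training would be unreliable — lower the thresholds"
        )

    ig_lengths = _empirical_intergenic_lengths(genes)
    if ig_lengths.size == 0:
        ig_lengths = np.arange(0, 201)  # no same-strand neighbours to learn from

    def draw_pseudo_len(gene: GeneAnnotation) -> int:
        cap = min(gene.length // 3, gene.length - 2 * config.min_subgene_len)
        return int(min(ig_lengths[rng.integers(ig_lengths.size)], max(cap, 0)))

    rows: list[dict[str, float]] = []
    labels: list[int] = []
    prov: list[dict] = []

    pos_genes = splittable[: config.class_cap]
    pos_draws: list[tuple[GeneAnnotation, int]] = []
    for g in pos_genes:
        p_len = draw_pseudo_len(g)
        pair = construct_positive_pair(g, coverage, p_len, config.min_subgene_len)
        rows.append(extract_features(pair, config.gap_threshold))
        labels.append(1)
        prov.append(
            {"source_gene": g.gene_id, "label": "positive", "pseudo_intergenic_len": p_len}
        )
        pos_draws.append((g, p_len))

    n_pos = len(pos_draws)
    if config.negatives_mode == "silent_donor":
        pool = find_silent_regions(genes, coverage, config.silent_threshold)
        if not pool:
            raise ValueError(
                "no silent donor regions below the silent threshold; raise "
                "silent_threshold or switch negatives_mode='opposite_strand'"
            )
        # mirror the positive geometry draws one-for-one, alternating the
        # two break topologies (full break / intergenic-only break)
        order = rng.permutation(n_pos)
        for k, idx in enumerate(order):
            g, p_len = pos_draws[idx]
            if k % 2 == 0 and p_len > 0:
                pair = construct_intergenic_break_pair(
                    g, pool, coverage, p_len, rng, config.min_subgene_len
                )
                kind = "negative_intergenic_break"
            else:
                pair = construct_negative_pair(
                    g, pool, coverage, p_len, rng, config.min_subgene_len
                )
                kind = "negative_full_break"
            rows.append(extract_features(pair, config.gap_threshold))
            labels.append(0)
            prov.append(
                {"source_gene": g.gene_id, "label": kind, "pseudo_intergenic_len": p_len}
            )
    elif config.negatives_mode == "opposite_strand":
        neg_pairs = _opposite_strand_pairs(genes, coverage)
        if not neg_pairs:
            raise ValueError("no adjacent opposite-strand pairs available as negatives")
        take = rng.permutation(len(neg_pairs))[:n_pos]
        for i in take:
            pair = neg_pairs[i]
            rows.append(extract_features(pair, config.gap_threshold))
            labels.append(0)
            prov.append(
                {
                    "source_gene": f"{pair.up_gene.gene_id}|{pair.down_gene.gene_id}",
                    "label": "negative",
                    "pseudo_intergenic_len": pair.intergenic_length,
                }
            )
    else:
        raise ValueError(f"unknown negatives_mode {config.negatives_mode!r}")

    X = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    y = np.asarray(labels, dtype=np.int64)

    # balance 1:1 by downsampling the larger class (deterministic)
    n_keep = min(int((y == 1).sum()), int((y == 0).sum()), config.class_cap)
    keep_idx = np.concatenate(
        [
            rng.permutation(np.flatnonzero(y == 1))[:n_keep],
            rng.permutation(np.flatnonzero(y == 0))[:n_keep],
        ]
    )
    keep_idx.sort()
    ts = TrainingSet(
        X=X.iloc[keep_idx].reset_index(drop=True),
        y=y[keep_idx],
        provenance=pd.DataFrame(prov).iloc[keep_idx].reset_index(drop=True),
    )
    logger.info(
        "training set: %d positives, %d negatives", (ts.y == 1).sum(), (ts.y == 0).sum()
    )
    return ts
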