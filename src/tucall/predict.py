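"""Genome-wide pair classification and TU concatenation.

Candidate pairs are adjacent same-strand genes with no other annotated
gene between them.  Same-strand neighbours separated by an intervening
gene (of either strand) are recorded as forced negatives: the
intervening transcription signal breaks the pair, and the classifier is
never asked about them.  Positive calls are transitively chained into
maximal transcription units; every gene ends up in exactly one TU
(single-gene TUs for everything unlinked), so the TU set is a partition
of the annotated genes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .core import ClassifiedPair, CoverageTrack, GeneAnnotation, GenePairRegion, TUCall
from .features import extract_features, feature_matrix
from .model import ModelBundle

logger = logging.getLogger(__name__)

__all__ = [
    "enumerate_candidate_pairs",
    "classify_pairs",
    "concatenate_tus",
    "tu_size_summary",
    "pairwise_f1",
]


def _make_pair(a: GeneAnnotation, b: GeneAnnotation) -> GenePairRegion:
    """Candidate region for genomically ordered same-strand genes a, b."""
    strand = a.strand
    up, down = (a, b) if strand == "+" else (b, a)  # 5' gene on the pair's strand
    ig_start, ig_end = a.end, b.start
    if ig_end < ig_start:  # overlapping genes: empty intergenic
        logger.info(
            "overlapping same-strand genes %s/%s: empty intergenic", a.gene_id, b.gene_id
        )
        ig_start = ig_end = min(a.end, b.start)
    return GenePairRegion(
        up_gene=up,
        down_gene=down,
        replicon=a.replicon,
        strand=strand,
        intergenic_start=ig_start,
        intergenic_end=ig_end,
    )


def enumerate_candidate_pairs(
    genes: Sequence[GeneAnnotation],
) -> tuple[list[GenePairRegion], list[tuple[GeneAnnotation, GeneAnnotation, str]]]:
    """All candidate adjacent same-strand pairs, plus forced negatives.

    Returns ``(candidates, forced_negatives)`` where each forced negative
    is ``(gene_a, gene_b, reason)`` for same-strand neighbours broken by
    an intervening annotated gene.
    """
    ordered = sorted(genes, key=lambda g: (g.replicon, g.start, g.end, g.gene_id))
    candidates: list[GenePairRegion] = []
    forced: list[tuple[GeneAnnotation, GeneAnnotation, str]] = []

    by_rep: dict[str, list[GeneAnnotation]] = {}
    for g in ordered:
        by_rep.setdefault(g.replicon, []).append(g)

    for gs in by_rep.values():
        for i in range(len(gs) - 1):
            a, b = gs[i], gs[i + 1]
            if a.strand == b.strand:
                candidates.append(_make_pair(a, b))
        # same-strand neighbours separated by >= 1 intervening gene
        for strand in ("+", "-"):
            sub = [g for g in gs if g.strand == strand]
            pos = {g.gene_id: i for i, g in enumerate(gs)}
            for a, b in zip(sub[:-1], sub[1:]):
                if pos[b.gene_id] - pos[a.gene_id] > 1:
                    forced.append((a, b, "intervening gene"))
    return candidates, forced


def classify_pairs(
    model: ModelBundle,
    pairs: Sequence[GenePairRegion],
    coverage: CoverageTrack,
    forced_negatives: Sequence[tuple[GeneAnnotation, GeneAnnotation, str]] = (),
) -> list[ClassifiedPair]:
    """Score every candidate pair with the trained model.

    Features are standardized with the model's stored parameters; forced
    negatives are appended with probability 0 and their reason.
    """
    out: list[ClassifiedPair] = []
    if pairs:
        for p in pairs:
            if p.replicon not in coverage:
                raise KeyError(f"replicon {p.replicon!r} missing from coverage")
            p.attach_coverage(coverage)
        X = feature_matrix(pairs, model.gap_threshold)
        proba = model.predict_proba(X)
        for p, feats, pr in zip(pairs, X.to_dict("records"), proba):
            out.append(
                ClassifiedPair(
                    pair=p,
                    features=feats,
                    probability=float(pr),
                    co_transcribed=bool(pr >= model.config.threshold),
                )
            )
    for a, b, reason in forced_negatives:
        up, down = (a, b) if a.strand == "+" else (b, a)
        region = GenePairRegion(
            up_gene=up,
            down_gene=down,
            replicon=a.replicon,
            strand=a.strand,
            intergenic_start=a.end,
            intergenic_end=max(b.start, a.end),
        )
        out.append(
            ClassifiedPair(
                pair=region, features={}, probability=0.0, co_transcribed=False, reason=reason
            )
        )
    return out


def concatenate_tus(
    genes: Sequence[GeneAnnotation], classified_pairs: Sequence[ClassifiedPair]
) -> list[TUCall]:
    """Chain positive pairs transitively into maximal TUs.

    Each gene belongs to exactly one TU (the output partitions the gene
    set); a positive pair that is not a candidate adjacency is a hard
    error — it signals an upstream bug.
    """
    ordered = sorted(genes, key=lambda g: (g.replicon, g.start, g.end, g.gene_id))
    candidates, _ = enumerate_candidate_pairs(ordered)
    candidate_keys = {
        frozenset((p.up_gene.gene_id, p.down_gene.gene_id)) for p in candidates
    }
    links: set[frozenset] = set()
    for cp in classified_pairs:
        if not cp.co_transcribed:
            continue
        key = frozenset((cp.up_id, cp.down_id))
        if key not in candidate_keys:
            raise ValueError(
                f"positive pair {cp.up_id}-{cp.down_id} is not a candidate adjacency"
            )
        links.add(key)

    tus: list[TUCall] = []
    by_rep: dict[str, list[GeneAnnotation]] = {}
    for g in ordered:
        by_rep.setdefault(g.replicon, []).append(g)

    for rep, gs in by_rep.items():
        current: list[GeneAnnotation] = []
        for g in gs:
            linked = (
                bool(current)
                and current[-1].strand == g.strand
                and frozenset((current[-1].gene_id, g.gene_id)) in links
            )
            if linked:
                current.append(g)
            else:
                if current:
                    tus.append(_close_tu(current, len(tus)))
                current = [g]
        if current:
            tus.append(_close_tu(current, len(tus)))
    return tus


def _close_tu(members: list[GeneAnnotation], index: int) -> TUCall:
    gene_ids = [g.gene_id for g in members]
    if members[0].strand == "-":
        gene_ids = gene_ids[::-1]  # report members 5'→3' on their own strand
    return TUCall(
        tu_id=f"TU{index + 1:05d}",
        replicon=members[0].replicon,
        strand=members[0].strand,
        gene_ids=gene_ids,
        start=min(g.start for g in members),
        end=max(g.end for g in members),
    )


def tu_size_summary(tus: Sequence[TUCall]) -> dict[str, int]:
    """Counts of single-gene, two-gene and >2-gene TUs."""
    sizes = np.array([t.n_genes for t in tus], dtype=int)
    return {
        "single_gene": int((sizes == 1).sum()),
        "two_gene": int((sizes == 2).sum()),
        "multi_gene": int((sizes > 2).sum()),
        "total": int(sizes.size),
    }


def pairwise_f1(
    predicted_positive: set[frozenset], true_positive: set[frozenset]
) -> dict[str, float]:
    """Precision/recall/F1 of predicted co-transcribed pairs vs truth."""
    tp = len(predicted_positive & true_positive)
    precision = tp / len(predicted_positive) if predicted_positive else float("nan")
    recall = tp / len(true_positive) if true_positive else float("nan")
    if not np.isfinite(precision) or not np.isfinite(recall) or precision + recall == 0:
        f1 = 0.0 if (predicted_positive or true_positive) else float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1}
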