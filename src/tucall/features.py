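"""Coverage continuity/stability features for a gene-pair region.

The classifier's premise is that read coverage inside a transcription
unit flows across the intergenic region as continuously and evenly as it
does inside a gene, whereas a TU boundary shows a coverage break.  The
twelve features below quantify that premise from the per-base depth of
the three parts of a :class:`~tucall.core.GenePairRegion` (upstream
gene, intergenic interval, downstream gene, all 5'→3' on the pair's
strand):

======================  =====================================================
name                    definition (m = mean depth, +1 pseudocounts throughout)
======================  =====================================================
log2_mean_up            log2(m_up + 1)
log2_mean_down          log2(m_down + 1)
log2_mean_intergenic    log2(m_ig + 1)
fold_change             \\|log2((m_up+1)/(m_down+1))\\|
gap_prop_pair           fraction of gap bases over the whole pair region
gap_prop_intergenic     fraction of gap bases in the intergenic part
gap_prop_up             fraction of gap bases in the upstream gene
gap_prop_down           fraction of gap bases in the downstream gene
intergenic_gap_run      longest gap run in the intergenic part / its length
expression_drop         (m_ig + 1) / (max(m_up, m_down) + 1)
cv_pair                 sd(depth) / (mean(depth)+1) over the whole region
cv_intergenic           sd(depth) / (mean(depth)+1) over the intergenic part
======================  =====================================================

A *gap* is a base with depth ≤ ``gap_threshold`` (default 0).  When the
two genes abut (empty intergenic interval) the intergenic statistics are
computed on the two junction bases — the last upstream base and the
first downstream base — so continuity across the junction is still
measured and no feature is ever NaN.
"""

from __future__ import annotations

import numpy as np

from .core import GenePairRegion

__all__ = [
    "FEATURE_NAMES",
    "gap_proportion",
    "longest_gap_run",
    "fold_change",
    "extract_features",
    "feature_matrix",
]

FEATURE_NAMES: tuple[str, ...] = (
    "log2_mean_up",
    "log2_mean_down",
    "log2_mean_intergenic",
    "fold_change",
    "gap_prop_pair",
    "gap_prop_intergenic",
    "gap_prop_up",
    "gap_prop_down",
    "intergenic_gap_run",
    "expression_drop",
    "cv_pair",
    "cv_intergenic",
)


def gap_proportion(depths: np.ndarray, gap_threshold: float = 0.0) -> float:
    """Fraction of positions with depth ≤ ``gap_threshold``; empty → 0."""
    depths = np.asarray(depths)
    if depths.size == 0:
        return 0.0
    return float(np.mean(depths <= gap_threshold))


def longest_gap_run(depths: np.ndarray, gap_threshold: float = 0.0) -> int:
    """Length of the longest maximal run of gap positions; empty → 0."""
    depths = np.asarray(depths)
    if depths.size == 0:
        return 0
    is_gap = np.concatenate(([0], (depths <= gap_threshold).astype(np.int8), [0]))
    edges = np.diff(is_gap)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if starts.size == 0:
        return 0
    return int(np.max(ends - starts))


def fold_change(mean1: float, mean2: float) -> float:
    """|log2((mean1+1)/(mean2+1))| — symmetric expression fold change."""
    return float(abs(np.log2((mean1 + 1.0) / (mean2 + 1.0))))


def _mean(depths: np.ndarray) -> float:
    return float(np.mean(depths)) if depths.size else 0.0


def _cv(depths: np.ndarray) -> float:
    # pseudocount in the denominator keeps all-zero segments at CV 0
    if depths.size == 0:
        return 0.0
    return float(np.std(depths) / (np.mean(depths) + 1.0))


def extract_features(
    pair: GenePairRegion, gap_threshold: float = 0.0
) -> dict[str, float]:
    """Compute all twelve features for one pair region.

    Requires coverage slices to be attached; raises if both sub-gene
    slices are empty (a malformed pair).
    """
    up = np.asarray(pair.up_cov, dtype=np.float64)
    ig = np.asarray(pair.intergenic_cov, dtype=np.float64)
    down = np.asarray(pair.down_cov, dtype=np.float64)
    if up.size == 0 and down.size == 0:
        raise ValueError("malformed pair: both sub-gene coverage slices are empty")

    whole = np.concatenate([up, ig, down])
    # empty intergenic: measure continuity across the junction itself
    if ig.size == 0:
        junction = []
        if up.size:
            junction.append(up[-1])
        if down.size:
            junction.append(down[0])
        ig_eff = np.asarray(junction, dtype=np.float64)
    else:
        ig_eff = ig

    m_up, m_down, m_ig = _mean(up), _mean(down), _mean(ig_eff)
    return {
        "log2_mean_up": float(np.log2(m_up + 1.0)),
        "log2_mean_down": float(np.log2(m_down + 1.0)),
        "log2_mean_intergenic": float(np.log2(m_ig + 1.0)),
        "fold_change": fold_change(m_up, m_down),
        "gap_prop_pair": gap_proportion(whole, gap_threshold),
        "gap_prop_intergenic": gap_proportion(ig_eff, gap_threshold),
        "gap_prop_up": gap_proportion(up, gap_threshold),
        "gap_prop_down": gap_proportion(down, gap_threshold),
        "intergenic_gap_run": longest_gap_run(ig_eff, gap_threshold)
        / max(ig_eff.size, 1),
        "expression_drop": (m_ig + 1.0) / (max(m_up, m_down) + 1.0),
        "cv_pair": _cv(whole),
        "cv_intergenic": _cv(ig_eff),
    }


def feature_matrix(pairs, gap_threshold: float = 0.0):
    """Feature table for a list of pairs (rows in input order)."""
    import pandas as pd

    rows = [extract_features(p, gap_threshold) for p in pairs]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))
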