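"""Shared domain types for transcription-unit calling.

Coordinate convention: everything inside the package is 0-based,
half-open ``[start, end)``.  GFF3 (1-based inclusive) and bedgraph
(0-based half-open) are converted only at the I/O boundary, and TU/pair
tables are written back 1-based inclusive for genome-browser users.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "Genome",
    "GeneAnnotation",
    "CoverageTrack",
    "GenePairRegion",
    "ClassifiedPair",
    "TUCall",
    "Metrics",
]


@dataclass(frozen=True)
class Genome:
    """Replicon names and lengths, optionally with raw sequence text."""

    lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"replicon {name!r} has non-positive length {n}")

    @property
    def replicons(self) -> list[str]:
        return list(self.lengths)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene/CDS.

    ``start``/``end`` are 0-based half-open (converted from GFF at read
    time).  ``strand`` is ``+`` or ``-``.
    """

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    locus_tag: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Per-base read depth, one array per replicon.

    Depth arrays are float64 internally (bedgraph values need not be
    integral) but are non-negative and length-matched to the replicon.
    """

    def __init__(self, data: Mapping[str, np.ndarray]):
        self.data: dict[str, np.ndarray] = {}
        for name, arr in data.items():
            a = np.asarray(arr, dtype=np.float64)
            if a.ndim != 1:
                raise ValueError(f"coverage for {name!r} must be 1-D")
            if a.size == 0:
                raise ValueError(f"coverage for {name!r} is empty")
            if np.any(a < 0):
                raise ValueError(f"coverage for {name!r} has negative depth")
            self.data[name] = a

    @property
    def replicons(self) -> list[str]:
        return list(self.data)

    def __getitem__(self, replicon: str) -> np.ndarray:
        return self.data[replicon]

    def __contains__(self, replicon: str) -> bool:
        return replicon in self.data

    def __iter__(self) -> Iterator[str]:
        return iter(self.data)

    def slice(self, replicon: str, start: int, end: int) -> np.ndarray:
        """Depth over ``[start, end)``; bounds-checked."""
        arr = self.data[replicon]
        if not (0 <= start <= end <= arr.size):
            raise IndexError(
                f"[{start}, {end}) outside replicon {replicon!r} of length {arr.size}"
            )
        return arr[start:end]

    def equals(self, other: "CoverageTrack") -> bool:
        return set(self.data) == set(other.data) and all(
            np.array_equal(self.data[k], other.data[k]) for k in self.data
        )


@dataclass
class GenePairRegion:
    """An (upstream gene, intergenic interval, downstream gene) triple.

    "Upstream" is 5' on the pair's own strand: for a ``-`` strand pair the
    upstream gene is the one with the *higher* genomic coordinate, and the
    coverage slices below are stored 5'→3' (i.e. reversed relative to the
    genome).  ``intergenic_start``/``intergenic_end`` stay in genomic
    orientation and may describe an empty interval (start == end) when the
    genes abut or overlap.

    Coverage slices are attached lazily (``attach_coverage``) so candidate
    pairs can be enumerated from annotation alone.
    """

    up_gene: GeneAnnotation
    down_gene: GeneAnnotation
    replicon: str
    strand: str
    intergenic_start: int
    intergenic_end: int
    up_cov: np.ndarray | None = None
    intergenic_cov: np.ndarray | None = None
    down_cov: np.ndarray | None = None
    source: str = "genome"  # genome | constructed_positive | constructed_negative

    @property
    def intergenic_length(self) -> int:
        return self.intergenic_end - self.intergenic_start

    def attach_coverage(self, track: CoverageTrack) -> "GenePairRegion":
        """Fill the three coverage slices from ``track``, oriented 5'→3'."""
        if self.replicon not in track:
            raise KeyError(f"replicon {self.replicon!r} missing from coverage track")
        up = track.slice(self.replicon, self.up_gene.start, self.up_gene.end)
        ig = track.slice(self.replicon, self.intergenic_start, self.intergenic_end)
        down = track.slice(self.replicon, self.down_gene.start, self.down_gene.end)
        if self.strand == "-":
            up, ig, down = up[::-1], ig[::-1], down[::-1]
        self.up_cov, self.intergenic_cov, self.down_cov = up, ig, down
        return self


@dataclass
class ClassifiedPair:
    """A candidate gene pair with its features and the model's verdict."""

    pair: GenePairRegion
    features: dict[str, float]
    probability: float
    co_transcribed: bool
    reason: str | None = None  # set for forced negatives (e.g. intervening gene)

    @property
    def up_id(self) -> str:
        return self.pair.up_gene.gene_id

    @property
    def down_id(self) -> str:
        return self.pair.down_gene.gene_id


@dataclass
class TUCall:
    """A maximal run of co-transcribed genes (possibly a single gene)."""

    tu_id: str
    replicon: str
    strand: str
    gene_ids: list[str]
    start: int  # 0-based half-open span over all member genes
    end: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class Metrics:
    """Confusion counts plus the derived rates.

    Rates with a zero denominator are ``nan`` (undefined), never 0.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        def _rate(num: int, den: int) -> float:
            return num / den if den > 0 else float("nan")

        object.__setattr__(self, "sensitivity", _rate(self.tp, self.tp + self.fn))
        object.__setattr__(self, "specificity", _rate(self.tn, self.tn + self.fp))
        total = self.tp + self.fn + self.tn + self.fp
        object.__setattr__(self, "accuracy", _rate(self.tp + self.tn, total))

    def as_dict(self) -> dict[str, float | int]:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }
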