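"""Readers and writers for the standard genomics formats.

All coordinate-convention conversions live here: GFF3 comes in 1-based
inclusive and is converted to the package-internal 0-based half-open
convention; bedgraph is already 0-based half-open; tables are written
back 1-based inclusive.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import ClassifiedPair, CoverageTrack, GeneAnnotation, Genome, TUCall
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "read_genome",
    "read_annotations",
    "compute_coverage",
    "read_wiggle",
    "write_bedgraph",
    "write_tu_bedgraphs",
    "write_tu_tables",
]


def read_genome(path: str | os.PathLike) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Duplicate record ids and empty files are hard errors.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise ValueError(f"duplicate FASTA record id {record.id!r}")
        seq = str(record.seq)
        lengths[record.id] = len(seq)
        sequences[record.id] = seq
    if not lengths:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(lengths=lengths, sequences=sequences)


def read_annotations(
    path: str | os.PathLike,
    genome: Genome | None = None,
    feature_types: Sequence[str] = ("gene", "CDS"),
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3, sorted by (replicon, start).

    When both a ``gene`` record and a child/locus-matched ``CDS`` describe
    the same locus, the gene wins.  Records with end < start are skipped
    with a warning; a replicon unknown to ``genome`` (when provided) is a
    hard error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    def _attr(feat, key: str) -> str | None:
        vals = feat.attributes.get(key)
        return vals[0] if vals else None

    genes: list[GeneAnnotation] = []
    seen_gene_keys: set[tuple] = set()  # loci already covered by a 'gene' record
    gene_ids: set[str] = set()
    deferred_cds = []

    wanted = set(feature_types)
    for feat in db.all_features():
        if feat.featuretype not in wanted:
            continue
        if feat.end < feat.start:
            logger.warning(
                "skipping %s record %s: end %d < start %d",
                feat.featuretype,
                _attr(feat, "ID") or "<no id>",
                feat.end,
                feat.start,
            )
            continue
        if genome is not None and feat.seqid not in genome.lengths:
            raise ValueError(
                f"annotation replicon {feat.seqid!r} not present in genome "
                f"(known: {sorted(genome.lengths)})"
            )
        if feat.strand not in ("+", "-"):
            logger.warning("skipping %s without strand", _attr(feat, "ID"))
            continue
        locus = _attr(feat, "locus_tag")
        gene_id = _attr(feat, "ID") or locus or f"{feat.seqid}:{feat.start}-{feat.end}"
        ann = GeneAnnotation(
            gene_id=gene_id,
            replicon=feat.seqid,
            start=feat.start - 1,  # GFF is 1-based inclusive
            end=feat.end,
            strand=feat.strand,
            locus_tag=locus,
        )
        if feat.featuretype == "gene":
            genes.append(ann)
            gene_ids.add(gene_id)
            if locus:
                seen_gene_keys.add(("locus", locus))
            seen_gene_keys.add(("span", feat.seqid, feat.strand, feat.start, feat.end))
        else:
            deferred_cds.append((feat, ann, locus))

    # keep a CDS only when no gene record covers the same locus
    for feat, ann, locus in deferred_cds:
        parent = feat.attributes.get("Parent", [None])[0]
        if parent and parent in gene_ids:
            continue
        if locus and ("locus", locus) in seen_gene_keys:
            continue
        if ("span", feat.seqid, feat.strand, feat.start, feat.end) in seen_gene_keys:
            continue
        genes.append(ann)

    genes.sort(key=lambda g: (g.replicon, g.start, g.end, g.gene_id))
    return genes


def compute_coverage(
    path: str | os.PathLike,
    genome: Genome,
    strand_mode: str = "unstranded",
    min_mapq: int = 0,
    library_reversed: bool = False,
) -> CoverageTrack:
    """Per-base depth from a sorted, indexed BAM.

    Depth at a base is the number of aligned-read blocks overlapping it
    after excluding unmapped, secondary, supplementary and duplicate
    reads (and reads below ``min_mapq`` if set).  Each mate of a pair
    contributes its own aligned interval.  Strand-specific modes assign a
    read to the strand of its fragment, inferred from the reverse flag
    (mate 2 flipped, and the whole library flipped when
    ``library_reversed`` is set).
    """
    import pysam

    if strand_mode not in ("unstranded", "forward", "reverse"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")

    with pysam.AlignmentFile(str(path), "rb") as bam:
        if not bam.has_index():
            raise ValueError(
                f"BAM {path} has no index; run 'samtools index' (or pysam.index) first"
            )
        bad = [r for r in bam.references if r not in genome.lengths]
        if bad:
            raise ValueError(
                f"BAM references not present in genome: {bad}; "
                f"genome has {sorted(genome.lengths)}"
            )
        diffs = {name: np.zeros(n + 1, dtype=np.int64) for name, n in genome.lengths.items()}
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            if read.mapping_quality < min_mapq:
                continue
            if strand_mode != "unstranded":
                frag_reverse = read.is_reverse
                if read.is_paired and read.is_read2:
                    frag_reverse = not frag_reverse
                if library_reversed:
                    frag_reverse = not frag_reverse
                if strand_mode == "forward" and frag_reverse:
                    continue
                if strand_mode == "reverse" and not frag_reverse:
                    continue
            diff = diffs[read.reference_name]
            for block_start, block_end in read.get_blocks():
                diff[block_start] += 1
                diff[block_end] -= 1

    return CoverageTrack(
        {name: np.cumsum(diff[:-1]).astype(np.float64) for name, diff in diffs.items()}
    )


def read_wiggle(path: str | os.PathLike, genome: Genome) -> CoverageTrack:
    """Read a bedgraph or wiggle (fixedStep/variableStep) text track.

    Unspecified positions get depth 0.  bedgraph intervals are 0-based
    half-open; wiggle positions are 1-based.  Intervals beyond the
    replicon length are hard errors.
    """
    data = {name: np.zeros(n, dtype=np.float64) for name, n in genome.lengths.items()}

    def _check(chrom: str, start0: int, end0: int) -> None:
        if chrom not in data:
            raise ValueError(f"track replicon {chrom!r} not present in genome")
        if start0 < 0 or end0 > data[chrom].size or start0 > end0:
            raise ValueError(
                f"interval [{start0}, {end0}) outside replicon {chrom!r} "
                f"of length {data[chrom].size}"
            )

    mode = "bedgraph"
    chrom = None
    span = 1
    step = 1
    pos = 0  # next 1-based position for fixedStep
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if fields[0] in ("variableStep", "fixedStep"):
                mode = fields[0]
                kv = dict(f.split("=", 1) for f in fields[1:])
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                if mode == "fixedStep":
                    pos = int(kv["start"])
                    step = int(kv.get("step", 1))
                continue
            if mode == "bedgraph":
                c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                _check(c, s, e)
                data[c][s:e] = v
            elif mode == "variableStep":
                p, v = int(fields[0]), float(fields[1])
                _check(chrom, p - 1, p - 1 + span)
                data[chrom][p - 1 : p - 1 + span] = v
            else:  # fixedStep
                v = float(fields[0])
                _check(chrom, pos - 1, pos - 1 + span)
                data[chrom][pos - 1 : pos - 1 + span] = v
                pos += step
    return CoverageTrack(data)


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _runs(arr: np.ndarray) -> Iterable[tuple[int, int, float]]:
    """Maximal runs of equal value as (start, end, value)."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate(([0], change, [arr.size]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        yield int(s), int(e), float(arr[s])


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a coverage track as bedgraph (zero-depth runs omitted)."""
    with open(path, "w") as fh:
        for name in track.replicons:
            for s, e, v in _runs(track[name]):
                if v == 0:
                    continue
                fh.write(f"{name}\t{s}\t{e}\t{_format_value(v)}\n")


def write_tu_bedgraphs(
    tus: Sequence[TUCall], forward_path: str | os.PathLike, reverse_path: str | os.PathLike
) -> None:
    """Write TU spans as two browser tracks.

    Forward-strand TUs get value +1, reverse-strand TUs value −1, so a
    genome browser shows them as bars above/below the axis.
    """
    for strand, path, value in (("+", forward_path, 1), ("-", reverse_path, -1)):
        rows = sorted(
            (t for t in tus if t.strand == strand), key=lambda t: (t.replicon, t.start)
        )
        with open(path, "w") as fh:
            for t in rows:
                fh.write(f"{t.replicon}\t{t.start}\t{t.end}\t{value}\n")


def _check_pairs_vs_tus(pairs: Sequence[ClassifiedPair], tus: Sequence[TUCall]) -> None:
    gene_to_tu: dict[str, TUCall] = {}
    for tu in tus:
        for g in tu.gene_ids:
            if g in gene_to_tu:
                raise ValueError(f"gene {g!r} appears in more than one TU")
            gene_to_tu[g] = tu
    for p in pairs:
        if not p.co_transcribed:
            continue
        tu_a = gene_to_tu.get(p.up_id)
        tu_b = gene_to_tu.get(p.down_id)
        if tu_a is None or tu_b is None or tu_a is not tu_b:
            raise ValueError(
                f"positive pair {p.up_id}-{p.down_id} not inside a single TU "
                "(concatenation inconsistency)"
            )
        ids = tu_a.gene_ids
        i, j = ids.index(p.up_id), ids.index(p.down_id)
        if abs(i - j) != 1:
            raise ValueError(
                f"positive pair {p.up_id}-{p.down_id} not adjacent within TU {tu_a.tu_id}"
            )


def write_tu_tables(
    pairs: Sequence[ClassifiedPair], tus: Sequence[TUCall], out_dir: str | os.PathLike
) -> tuple[str, str]:
    """Write the pair-level and TU-level TSV result tables.

    Pairs and TUs must be consistent (every positive pair adjacent inside
    exactly one TU) — an inconsistency signals a concatenation bug and is
    a hard error.  Returns the two file paths.
    """
    _check_pairs_vs_tus(pairs, tus)
    os.makedirs(out_dir, exist_ok=True)

    pair_rows = []
    for p in pairs:
        row = {
            "gene1": p.up_id,
            "gene2": p.down_id,
            "replicon": p.pair.replicon,
            "strand": p.pair.strand,
        }
        row.update({name: p.features.get(name, float("nan")) for name in FEATURE_NAMES})
        row["probability"] = p.probability
        row["call"] = "co-transcribed" if p.co_transcribed else "not"
        pair_rows.append(row)
    pair_path = os.path.join(out_dir, "gene_pairs.tsv")
    pd.DataFrame(pair_rows).to_csv(pair_path, sep="\t", index=False, float_format="%.6g")

    tu_rows = [
        {
            "tu_id": t.tu_id,
            "replicon": t.replicon,
            "strand": t.strand,
            "start": t.start + 1,  # 1-based inclusive for browsers
            "end": t.end,
            "n_genes": t.n_genes,
            "genes": ",".join(t.gene_ids),
        }
        for t in tus
    ]
    tu_path = os.path.join(out_dir, "transcription_units.tsv")
    pd.DataFrame(tu_rows).to_csv(tu_path, sep="\t", index=False)
    return pair_path, tu_path
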