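"""Synthetic bacterial replicon, annotation, coverage and TU ground truth.

The generator reproduces the statistical structure the classifier relies
on: genes grouped into transcription units laid left-to-right along one
replicon, continuous overdispersed (negative-binomial) depth across each
expressed TU span — including its within-TU intergenic bases — smoothed
on the read-length scale, and low/gappy background (Poisson) depth in
the spacers between TUs.  Everything is deterministic per seed and can
be exported as FASTA + GFF3 + bedgraph + a ground-truth table so the
whole pipeline is testable without any external download.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import CoverageTrack, GeneAnnotation, Genome

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_coverage",
    "simulate_dataset",
    "export_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic replicon.

    Defaults sketch a typical bacterial transcriptome: TU sizes are
    geometric (p=0.6 → mean ≈1.6 genes, mostly single-gene TUs, as real
    TU catalogs show), gene lengths log-normal with median ~900 bp,
    within-TU intergenic gaps short (geometric, mean ~40 bp) versus
    between-TU spacers (mean ~200 bp), per-TU expression log-normal
    around depth ~50 with negative-binomial per-base noise (dispersion
    r=10) smoothed over a 100 bp window to mimic read-length
    autocorrelation, and a faint Poisson background (ε=0.1) outside
    transcribed spans.
    """

    n_genes: int = 300
    p_tu: float = 0.6
    max_tu_size: int = 10
    gene_len_median: float = 900.0
    gene_len_sigma: float = 0.4
    intra_intergenic_mean: float = 40.0
    spacer_mean: float = 200.0
    expr_median: float = 50.0
    expr_sigma: float = 0.6
    expr_min: float = 0.0
    frac_silent: float = 0.1
    nb_dispersion: float = 10.0
    smooth_window: int = 100
    background_eps: float = 0.1
    p_forward: float = 0.5
    replicon: str = "chrSim"
    max_genome_len: int = 20_000_000

    def __post_init__(self) -> None:
        if not (0.0 < self.p_tu <= 1.0):
            raise ValueError("p_tu must be in (0, 1]")
        if self.background_eps < 0:
            raise ValueError("background_eps must be >= 0")
        if self.nb_dispersion <= 0 or self.smooth_window < 1:
            raise ValueError("invalid noise parameters")

    @classmethod
    def clear_regime(cls, **overrides) -> "SimConfig":
        """The unambiguous-signal condition: every TU expressed at depth
        ≥20, no background depth, no silent TUs."""
        base = dict(expr_min=20.0, frac_silent=0.0, background_eps=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """True TU partition, per-gene expression and TU spans."""

    tus: list[list[str]]  # gene ids per TU, genomic order
    gene_tu: dict[str, int]  # gene id → TU index
    tu_expression: list[float]  # mean depth; 0.0 for silent TUs
    tu_spans: list[tuple[int, int]]  # genomic span of each TU (0-based half-open)
    gene_expression: dict[str, float] = field(default_factory=dict)

    def true_pair_labels(self, genes: list[GeneAnnotation]) -> dict[frozenset, bool]:
        """Label every candidate adjacency: co-transcribed iff same TU."""
        from .predict import enumerate_candidate_pairs

        candidates, _ = enumerate_candidate_pairs(genes)
        return {
            frozenset((p.up_gene.gene_id, p.down_gene.gene_id)): (
                self.gene_tu[p.up_gene.gene_id] == self.gene_tu[p.down_gene.gene_id]
            )
            for p in candidates
        }


def _truncated_geometric(rng: np.random.Generator, p: float, max_val: int) -> int:
    return int(min(rng.geometric(p), max_val))


def simulate_annotation(
    config: SimConfig, seed: int
) -> tuple[Genome, list[GeneAnnotation], GroundTruth]:
    """Lay out genes and TUs along one replicon; deterministic per seed."""
    rng = np.random.default_rng(seed)

    sizes: list[int] = []
    total = 0
    while total < config.n_genes:
        k = _truncated_geometric(rng, config.p_tu, config.max_tu_size)
        k = min(k, config.n_genes - total)
        sizes.append(k)
        total += k

    genes: list[GeneAnnotation] = []
    tus: list[list[str]] = []
    gene_tu: dict[str, int] = {}
    tu_expression: list[float] = []
    tu_spans: list[tuple[int, int]] = []
    gene_expression: dict[str, float] = {}

    mu_len = math.log(config.gene_len_median)
    mu_expr = math.log(config.expr_median)
    cursor = 500
    gene_no = 0
    for tu_idx, size in enumerate(sizes):
        cursor += int(rng.geometric(1.0 / config.spacer_mean))
        strand = "+" if rng.random() < config.p_forward else "-"
        if rng.random() < config.frac_silent:
            expr = 0.0
        else:
            expr = float(np.exp(rng.normal(mu_expr, config.expr_sigma)))
            expr = max(expr, config.expr_min)
        span_start = cursor
        members: list[str] = []
        for j in range(size):
            if j > 0:
                cursor += int(rng.geometric(1.0 / config.intra_intergenic_mean))
            length = max(int(np.exp(rng.normal(mu_len, config.gene_len_sigma))), 60)
            gene_no += 1
            gid = f"sg{gene_no:04d}"
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    replicon=config.replicon,
                    start=cursor,
                    end=cursor + length,
                    strand=strand,
                    locus_tag=gid,
                )
            )
            members.append(gid)
            gene_tu[gid] = tu_idx
            gene_expression[gid] = expr
            cursor += length
        tus.append(members)
        tu_expression.append(expr)
        tu_spans.append((span_start, cursor))

    genome_len = cursor + 500
    if genome_len > config.max_genome_len:
        raise ValueError(
            f"simulated genome length {genome_len} exceeds max_genome_len "
            f"{config.max_genome_len}"
        )
    genome = Genome(lengths={config.replicon: genome_len})
    truth = GroundTruth(
        tus=tus,
        gene_tu=gene_tu,
        tu_expression=tu_expression,
        tu_spans=tu_spans,
        gene_expression=gene_expression,
    )
    return genome, genes, truth


def _nb_depth(
    rng: np.random.Generator, mean: float, r: float, n: int, window: int
) -> np.ndarray:
    """Negative-binomial per-base depth, moving-average smoothed.

    NB(mean μ, dispersion r) sampled as Poisson with Gamma(r, μ/r) rates;
    Var = μ + μ²/r, the Poisson limit as r→∞.  Smoothing uses edge
    replication so the mean is preserved at TU boundaries.
    """
    lam = rng.gamma(shape=r, scale=mean / r, size=n)
    raw = rng.poisson(lam).astype(np.float64)
    if window > 1:
        raw = uniform_filter1d(raw, size=window, mode="nearest")
    return np.rint(raw)


def simulate_coverage(
    genome: Genome,
    truth: GroundTruth,
    config: SimConfig,
    seed: int,
) -> CoverageTrack:
    """Per-base depth realizing the TU continuity premise.

    Expressed TU spans (genes plus their within-TU intergenic bases) get
    smoothed negative-binomial depth at the TU's expression level; all
    other bases — spacers and silent TUs — get Poisson background.
    """
    rng = np.random.default_rng(seed)
    n = genome.lengths[config.replicon]
    if config.background_eps > 0:
        depth = rng.poisson(config.background_eps, size=n).astype(np.float64)
    else:
        depth = np.zeros(n, dtype=np.float64)
    for (s, e), expr in zip(truth.tu_spans, truth.tu_expression):
        if expr <= 0:
            continue
        depth[s:e] = _nb_depth(rng, expr, config.nb_dispersion, e - s, config.smooth_window)
    return CoverageTrack({config.replicon: depth})


def simulate_dataset(
    config: SimConfig, seed: int
) -> tuple[Genome, list[GeneAnnotation], GroundTruth, CoverageTrack]:
    """Annotation + coverage in one call (seed split between the two)."""
    genome, genes, truth = simulate_annotation(config, seed)
    coverage = simulate_coverage(genome, truth, config, seed + 1_000_003)
    return genome, genes, truth, coverage


def export_fixture(
    genome: Genome,
    genes: list[GeneAnnotation],
    truth: GroundTruth,
    coverage: CoverageTrack,
    out_dir: str | os.PathLike,
    seed: int = 0,
) -> dict[str, str]:
    """Write FASTA, GFF3, bedgraph and ground-truth TSV for a fixture.

    The FASTA sequence is random (depth features never read it); the
    trio round-trips unchanged through the io readers.
    """
    from . import io as tio

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gff": os.path.join(out_dir, "annotation.gff3"),
        "bedgraph": os.path.join(out_dir, "coverage.bedgraph"),
        "truth": os.path.join(out_dir, "ground_truth.tsv"),
    }

    with open(paths["fasta"], "w") as fh:
        for name, length in genome.lengths.items():
            seq = "".join(rng.choice(list("ACGT"), size=length))
            fh.write(f">{name}\n")
            for i in range(0, length, 70):
                fh.write(seq[i : i + 70] + "\n")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.lengths.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.replicon, g.start)):
            fh.write(
                f"{g.replicon}\ttucall-sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};locus_tag={g.locus_tag}\n"
            )

    tio.write_bedgraph(coverage, paths["bedgraph"])

    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\ttu_index\ttu_expression\n")
        for g in sorted(genes, key=lambda g: (g.replicon, g.start)):
            ti = truth.gene_tu[g.gene_id]
            fh.write(f"{g.gene_id}\t{ti}\t{truth.tu_expression[ti]:.6g}\n")
    return paths
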