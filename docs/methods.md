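# Methods

## The model

`tucall` treats bacterial TU prediction as binary classification of
adjacent same-strand gene pairs, followed by transitive chaining. The
underlying assumption is biological: within a transcription unit the
RNA-seq depth signal flows across the intergenic region as continuously
and stably as it does within a gene, whereas a TU boundary (terminator +
promoter) shows a coverage break. Two further modelling assumptions are
inherited from the pair formulation: a gene belongs to exactly one TU
(the output is a partition; condition-dependent *alternative* TUs that
share genes are out of scope), and co-transcription is transitive, so
positive pairs can be chained into maximal runs.

Candidate pairs are consecutive same-strand genes with no intervening
annotated gene on either strand. Same-strand neighbours separated by an
intervening gene are *forced negatives*: the intervening transcription
signal belongs to a different unit, and asking the classifier about the
flanks would conflate two intergenic regions. Minus-strand pairs are
oriented 5′→3′ on their own strand before feature extraction (the
upstream gene is the higher-coordinate one, slices reversed), so the
feature semantics of "upstream/downstream" are strand-symmetric.

## Features

Twelve statistics of the per-base depth over (upstream sub-region,
intergenic interval, downstream sub-region); see the README table. Notes
on conventions, chosen to make every feature total (no NaN on any
input):

- a *gap* is a base with depth ≤ τ; τ defaults to 0 (a gap is an
  uncovered base), configurable for noisy backgrounds;
- +1 pseudocounts in every log/ratio; the coefficient of variation is
  sd/(mean+1);
- empty intergenic interval (abutting/overlapping genes): intergenic
  statistics are computed on the two junction bases, which still measure
  continuity across the junction;
- the expression drop is (m_I+1)/(max(m₁,m₂)+1) — relative to the
  *stronger* flank, so a silent downstream gene cannot mask an
  intergenic break.

Depth-scaling leaves the gap features exactly invariant and the
log-ratio features asymptotically invariant, so library size mostly
cancels; the absolute log-depth features intentionally retain expression
level, which carries real information (silent vs expressed).

## Constructed training data

Positives: every gene with length ≥ `min_gene_len` (600 bp), mean depth
≥ `min_mean_depth` (5×) and gap proportion ≤ `max_gap_prop` (0.1) is
split into two sub-genes (each ≥ 150 bp) around a centered
pseudo-intergenic window. The window keeps the gene's own observed
depth — that is the point: intragenic coverage *is* the transcribed-
intergenic case. Window lengths are drawn from the empirical
distribution of real same-strand adjacent intergenic distances,
truncated to what the gene's length allows (≤ ⌊L/3⌋ and leaving both
sub-genes ≥ 150 bp), so constructed pairs match the geometry of real
candidate pairs. One pair per gene, classes balanced 1:1, at most
`class_cap` (2000) per class.

Negatives re-use the positive split geometry one-for-one and splice in
depth from *silent donor regions* (annotated intergenic intervals or
genes with mean depth < `silent_threshold`, default 1×), in two
alternating topologies:

- **full break** — intergenic window and downstream sub-gene both from
  the donor (transcription ends after the upstream gene);
- **intergenic break** — only the window from the donor, both sub-genes
  keep the real expressed coverage (two expressed units separated by a
  quiet gap).

The mix matters. With full-break negatives alone, the negative class is
perfectly confounded with "silent downstream flank", and the trained SVM
also keys on downstream-expression features; genome-wide pairs that
straddle two *expressed* TUs then sit between both training clusters
and receive probabilities near 0.5, costing precision. Adding the
intergenic-break topology puts the label on the break itself and removes
the confound. A `negatives_mode="opposite_strand"` fallback uses real
adjacent opposite-strand pairs instead, for data sets with no silent
regions at all.

## Classifier

Random-forest RFE: fit a 100-tree forest, drop the feature with the
smallest mean-decrease-in-impurity importance, repeat until eight
remain. One feature per round keeps the elimination order
interpretable; rows are canonically sorted before each fit so the
selection is invariant to input order. The SVM is RBF-kernel, C = 1,
gamma = 1/(n_features·Var), on z-scored features; the 0.5 posterior
threshold calls a pair co-transcribed. Reported metrics are pooled
out-of-fold counts from a stratified 5-fold CV with fold-local
standardization. By default RFE runs once on the full training set and
CV measures only the SVM — the conventional, slightly optimistic
shortcut; `honest_cv=True` repeats RFE inside each training fold.
Note the CV metrics describe held-out *constructed* pairs, not real
genome truth; the simulator's ground-truth pairwise F1 is the honest
end-to-end measure.

Model persistence (`ModelBundle.save/load`) writes a single `.npz` of
JSON metadata plus numeric arrays (selected features, standardization
parameters, CV confusion, and the raw selected-feature training
matrix); loading re-fits the SVM deterministically from the stored
matrix and seed, so no opaque estimator state is serialized and a
loaded bundle reproduces probabilities bit-for-bit.

## Coverage semantics

Depth at a base counts aligned read blocks overlapping it, excluding
unmapped/secondary/supplementary/duplicate records; no MAPQ filter by
default. Spliced/clipped segments contribute only their aligned blocks;
each mate of a pair contributes its own interval (no fragment fill).
Libraries are treated as unstranded by default; strand-specific modes
assign fragments by flag orientation with a `library_reversed` switch.
Internally every coordinate is 0-based half-open; GFF3 (1-based
inclusive) and bedgraph (0-based half-open) are converted only at the
I/O boundary, and output tables are 1-based inclusive.

## The simulator

`simulate` generates what the method assumes, with each piece matched
to a typical bacterial transcriptome: TU sizes geometric (p = 0.6,
truncated at 10; mean ≈ 1.6 genes, mostly single-gene TUs as in real TU
catalogs), gene lengths log-normal (median 900 bp, σ = 0.4), within-TU
intergenic gaps geometric with mean 40 bp versus between-TU spacers with
mean 200 bp, per-TU expression log-normal (median 50×, σ = 0.6) with a
10% silent fraction, and per-base negative-binomial noise (dispersion
r = 10, sampled Gamma–Poisson) smoothed by a 100 bp moving average to
mimic read-length autocorrelation, over the *whole* TU span including
its internal intergenic bases. Untranscribed bases draw Poisson
background (ε = 0.1). `SimConfig.clear_regime()` is the unambiguous
condition used for end-to-end recovery checks: every TU expressed at
≥ 20×, no silent TUs, ε = 0.

What the simulator does **not** emulate: overlapping or nested genes,
operon-internal promoters/terminators (partial continuity), condition-
dependent alternative TUs, 5′/3′ UTR signal outside annotated genes,
coverage biases (GC, positional ramp), or read-level artifacts —
fixtures are depth tracks, not reads (a toy BAM writer in the tests
covers the pileup path). Passing the recovery tests therefore shows the
machinery is correct under the model's own premise, not that real-data
accuracy will match; on real libraries the background, UTR bleed-through
and partial terminators make the problem genuinely harder.

With background noise present, the silent-donor cutoff should scale
with the background level (regions can no longer have mean depth < 1
when ε ≥ 1); the degradation analyses in the test suite raise
`silent_threshold` to max(1, 3ε) for exactly this reason, and a τ > 0
gap threshold is the analogous knob for very deep libraries.

## Numerical/degenerate-input choices

Empty depth arrays: gap proportion 0, longest run 0, CV 0; a pair with
both sub-gene slices empty is rejected. Zero-variance features pass
through standardization unscaled. RFE importance ties break
lexicographically by feature name. Bedgraph output merges equal-value
runs and omits zero runs, which makes write∘read the identity on
tracks (unspecified bases are 0). Donor regions shorter than the
needed slice are tiled. All randomness flows from explicit
`numpy.random.default_rng` seeds; training-set construction, feature
selection, CV and the SVM's probability calibration are deterministic
given the seed, and outputs are byte-reproducible.

## Problem sizes

The test-suite and acceptance runs use simulated replicons of 40–300
genes (≈50–350 kb) and training sets of a few hundred pairs — large
enough that class balance, feature selection and chaining behave as at
genome scale, while a full pipeline run stays in seconds. A real
bacterial genome (~4,000 genes) runs the identical code path; cost
grows linearly in genome length for features and roughly quadratically
in training-set size for the SVM (capped by `class_cap`).
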