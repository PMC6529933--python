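"""Full run: simulate, train, classify gene pairs, concatenate TUs.

Compares the predicted co-transcribed pairs with the simulation's
ground-truth TU partition and prints the TU size breakdown.
"""

from tucall import (
    ModelConfig,
    SimConfig,
    TrainConfig,
    classify_pairs,
    concatenate_tus,
    enumerate_candidate_pairs,
    fit,
    pairwise_f1,
    simulate_dataset,
    tu_size_summary,
)
from tucall.trainset import build_training_set

config = SimConfig.clear_regime(n_genes=300)
_, genes, truth, coverage = simulate_dataset(config, seed=3)

train_set = build_training_set(genes, coverage, TrainConfig(), seed=3)
bundle = fit(train_set.X, train_set.y, ModelConfig(), seed=3)

candidates, forced = enumerate_candidate_pairs(genes)
classified = classify_pairs(bundle, candidates, coverage, forced)
tus = concatenate_tus(genes, classified)

labels = truth.true_pair_labels(genes)
predicted = {frozenset((c.up_id, c.down_id)) for c in classified if c.co_transcribed}
truth_pairs = {k for k, v in labels.items() if v}
score = pairwise_f1(predicted, truth_pairs)
summary = tu_size_summary(tus)

print(f"candidate pairs : {len(candidates)} (+{len(forced)} forced negative)")
print(f"co-transcribed  : {len(predicted)} predicted vs {len(truth_pairs)} true")
print(f"pairwise scores : precision {score['precision']:.3f}, "
      f"recall {score['recall']:.3f}, F1 {score['f1']:.3f}")
print(f"TUs             : {summary['total']} total = {summary['single_gene']} single-gene"
      f" + {summary['two_gene']} two-gene + {summary['multi_gene']} larger")
# Every gene lands in exactly one TU, so total TUs = genes − positive pairs.
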