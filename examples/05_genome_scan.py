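"""Scan a synthetic genome for enhancers and test gene-level enrichment.

1000-bp windows advancing by 500 bp tile a 2 x 100 kb annotated genome;
windows with >= 50% coding overlap are excluded, the rest scored with the
trained model at the calibrated 5% FPR cutoff.  Predictions are associated
with host genes (intronic) or nearest genes (intergenic), and the overlap
with the planted target-gene set is tested with an exact binomial tail.
"""

import cisclassify as cc

signal = cc.make_random_pwms(3, seed=11, prefix="signal")
decoys = cc.make_random_pwms(50, seed=12, prefix="decoy")
pwms = signal + decoys
world = cc.build_synthetic_world(2, 100_000, 90, 20, signal, decoys, seed=21)
positives, _ = cc.make_positives(40, signal, seed=13)
exclusions = [c for g in world.annotations for c in g.cds_intervals] + list(
    world.planted_enhancers
)
controls = cc.sample_matched_controls(positives, world.genome, exclusions, n=500, seed=14)
features = cc.build_feature_matrix(
    positives + controls, pwms, labels=[1] * len(positives) + [-1] * len(controls)
)
cutoff, model = cc.calibrate_fpr_cutoff(features, fpr=0.05, seed=15)

windows = cc.make_windows(world.genome, world.annotations)
windows = cc.score_windows(windows, world.genome, model, pwms)
predictions = [w for w in windows if w.is_prediction]
recovered = sum(
    1
    for enh in world.planted_enhancers
    if any(p.interval.overlap_length(enh) >= 500 for p in predictions)
)
print(f"windows scored: {len(windows)}; predictions: {len(predictions)}")
print(f"planted enhancers recovered: {recovered}/{len(world.planted_enhancers)}")

mapping = cc.associate_genes(predictions, world.annotations)
genes = [g for g in mapping.values() if g is not None]
p0 = len(world.fc_gene_ids) / len(world.annotations)
res = cc.enrichment_test(genes, world.fc_gene_ids, background_rate=p0)
print(f"distinct associated genes: {res.tested}; in target set: {res.observed}")
print(f"fold enrichment: {res.fold:.2f}, binomial p = {res.p_value:.2e}")
# Recovery near 100% with a significant gene-level enrichment shows the
# classifier transfers from isolated training sequences to a genome context.
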