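"""Train the enhancer classifier, rank motifs, and calibrate the scan cutoff.

Forty planted positives and matched controls are represented as per-bp
motif-match densities over 3 signal + 50 decoy PWMs.  A class-cost-balanced
linear SVM separates them; |w|-based ranking over 100 random partitions
should place the signal motifs at the top, and the 5% FPR cutoff is read
off pooled held-out control scores.
"""

import cisclassify as cc

signal = cc.make_random_pwms(3, seed=11, prefix="signal")
decoys = cc.make_random_pwms(50, seed=12, prefix="decoy")
pwms = signal + decoys

positives, _ = cc.make_positives(40, signal, seed=13)
world = cc.build_synthetic_world(2, 100_000, 90, 20, signal, decoys, seed=21)
exclusions = [c for g in world.annotations for c in g.cds_intervals] + list(
    world.planted_enhancers
)
controls = cc.sample_matched_controls(positives, world.genome, exclusions, n=500, seed=14)

features = cc.build_feature_matrix(
    positives + controls, pwms, labels=[1] * len(positives) + [-1] * len(controls)
)
roc, _ = cc.cross_validate(features, k=10, seed=5)
print(f"pooled 10-fold CV AUC: {roc.auc:.3f}")

ranked = cc.rank_motifs(features, n_partitions=100, seed=5)
print("top 5 motifs by median |w| rank:")
for r in ranked[:5]:
    print(f"  {r.motif_id}: median rank {r.median_rank:.0f}, "
          f"weight share {r.weight_share:.3f}, sign {r.sign}")
print(f"features holding >50% of sum|w|: "
      f"{cc.weight_concentration(cc.train_svm(features).weights)}")

cutoff, model = cc.calibrate_fpr_cutoff(features, fpr=0.05, seed=15)
print(f"5% FPR decision cutoff: {cutoff:.3f}")
# The three signal motifs should dominate the ranking; the cutoff is what
# the genome scan uses to call windows as predicted enhancers.
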