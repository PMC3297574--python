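"""Analyze the TFBS-class composition of an enhancer set.

Each enhancer is reduced to a boolean vector of motif-class presence;
uniqueness of rows, the maximum fraction of enhancers sharing any N
classes, and hierarchical clustering (Ward linkage on binary distances)
summarize how combinatorial the class's regulatory grammar is.
"""

import cisclassify as cc
from cisclassify.combinatorics import MotifClass, linkage_to_newick

signal = cc.make_random_pwms(4, seed=11, prefix="tf")
# plant different motif subsets into different enhancers
import numpy as np

rng = np.random.default_rng(3)
enhancers = []
for i in range(8):
    rec = cc.sample_background(600, 0.43, seed=400 + i)
    rec.id = f"enh_{i}"
    subset = [p for p in signal if rng.random() < 0.6]
    for pwm in subset:
        rec, _ = cc.plant_motifs(rec, [pwm], 2, seed=int(rng.integers(0, 2**31)))
    enhancers.append(rec)

classes = [MotifClass(p.id, [p.id]) for p in signal]
m = cc.composition_matrix(enhancers, classes, signal)
print("presence matrix (enhancers x classes):")
for eid, row in zip(m.enhancer_ids, m.presence.astype(int)):
    print(f"  {eid}: {row}")

print(f"distinct class combinations: {cc.unique_combination_count(m)}/8")
for n in range(1, 5):
    print(f"max fraction sharing {n} classes: {cc.max_shared_fraction(m, n):.2f}")

merge = cc.cluster_rows(m.presence, "binary_jaccard", "ward")
print("dendrogram:", linkage_to_newick(merge, m.enhancer_ids))
# Many distinct rows with a fast-decaying shared-fraction curve indicate a
# combinatorial grammar: no single class subset explains the whole set.
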