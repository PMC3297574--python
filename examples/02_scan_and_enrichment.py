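"""Scan sequences for PWM matches and test motif over-representation.

Match calls use an exact per-position p-value of the log-odds score under
the background mononucleotide model (default gate p <= 1e-4, both strands).
Enrichment of a motif in a query set versus background sequences is tested
per-sequence (presence/absence) with a one-sided Fisher exact test and
Benjamini-Hochberg correction.
"""

import cisclassify as cc

signal = cc.make_random_pwms(1, seed=11, prefix="signal")
query, _ = cc.make_positives(12, signal, seed=61, min_copies=2, max_copies=3)
background = [cc.sample_background(1000, 0.43, seed=62 + i) for i in range(12)]
for i, rec in enumerate(background):
    rec.id = f"bg_{i}"

matches = cc.scan_sequence(query[0], signal[0])
print(f"{query[0].id}: {len(matches)} matches to {signal[0].id}")
for m in matches:
    print(f"  offset {m.offset} strand {m.strand} score {m.score:.2f} bits "
          f"p {m.p_value:.2e}")
print(f"match density: {cc.count_per_bp(matches, query[0]):.4f} per bp")

(result,) = cc.fisher_overrepresentation(query, background, signal)
print(f"\n{result.motif_id}: {result.count_query}/{result.n_query} query vs "
      f"{result.count_background}/{result.n_background} background sequences "
      f"with >= 1 match; Fisher p = {result.p_value:.2e}, BH q = {result.q_value:.2e}")
# A small p/q indicates the motif occurs in more query sequences than
# expected from the background rate — the criterion used to nominate TFs.
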