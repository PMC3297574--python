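"""Sample-size and ortholog-augmentation study.

For each training-set size, a classifier trained only on reference-species
positives ("dm_only") is compared against one additionally trained with up
to two orthologs per sampled positive ("with_orthologs").  Validation folds
and the held-out "true AUC" evaluation contain reference-species sequences
only, so the two conditions are scored on identical data and can be paired
replicate-by-replicate for a Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .classifier import (
    DEFAULT_C,
    FeatureMatrix,
    build_feature_matrix,
    cross_validate,
    roc_from_scores,
    train_svm,
)
from .motifs import DEFAULT_P_THRESHOLD, Pwm
from .records import SequenceRecord

CONDITIONS = ("dm_only", "with_orthologs")


@dataclass
class EvalRecord:
    sample_size: int
    condition: str
    replicate: int
    auc_cv: float
    auc_true: float
    tested_ids: set[str] = field(default_factory=set)
    positive_ids: set[str] = field(default_factory=set)

    @property
    def recognized_ids(self) -> set[str]:
        return set(self.positive_ids)


def signed_rank_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p on paired samples; exact null for
    <= 25 informative pairs, normal approximation with continuity correction
    above; all-zero differences give p = 1.0 by convention."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("unpaired samples")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    if nonzero.size <= 25:
        try:
            return float(wilcoxon(x, y, zero_method="wilcox", method="exact").pvalue)
        except ValueError:
            pass
    return float(
        wilcoxon(x, y, zero_method="wilcox", method="approx", correction=True).pvalue
    )


def sample_size_experiment(
    pool_positives: Sequence[SequenceRecord],
    ortholog_map: Mapping[str, Sequence[SequenceRecord]],
    controls: Sequence[SequenceRecord],
    pwms: Sequence[Pwm],
    sizes: Sequence[int] = tuple(range(10, 65, 5)),
    replicates: int = 100,
    max_orthologs: int = 2,
    C: float = DEFAULT_C,
    seed: int = 0,
    controls_per_positive: int = 10,
    k_folds: int = 10,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    features: Optional[FeatureMatrix] = None,
) -> list[EvalRecord]:
    """Per replicate and size: sample positives, build both conditions on
    the same sample, cross-validate (orthologs never enter test folds), and
    measure the true AUC on the positives excluded from the sample against
    held-out controls.  Features are computed once for the whole pool."""
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    if len(pool_positives) < max(sizes):
        raise ValueError(
            f"positive pool ({len(pool_positives)}) smaller than max size {max(sizes)}"
        )
    all_orth = [o for enh in pool_positives for o in ortholog_map.get(enh.id, [])]
    if features is None:
        everything = list(pool_positives) + all_orth + list(controls)
        labels = [1] * (len(pool_positives) + len(all_orth)) + [-1] * len(controls)
        features = build_feature_matrix(everything, pwms, p_threshold, labels=labels)
    row = {sid: i for i, sid in enumerate(features.sequence_ids)}
    pos_ids = [p.id for p in pool_positives]
    ctrl_ids = [c.id for c in controls]
    orth_rows_by_pos = {
        enh.id: [row[o.id] for o in ortholog_map.get(enh.id, [])]
        for enh in pool_positives
    }

    records: list[EvalRecord] = []
    master = np.random.SeedSequence(seed)
    for size in sizes:
        for rep in range(replicates):
            rng = np.random.default_rng(master.spawn(1)[0])
            sample = list(rng.choice(len(pos_ids), size=size, replace=False))
            sampled_ids = [pos_ids[i] for i in sample]
            held_pos = [row[pid] for pid in pos_ids if pid not in set(sampled_ids)]
            n_train_ctrl = min(controls_per_positive * size, len(ctrl_ids) // 2)
            ctrl_perm = rng.permutation(len(ctrl_ids))
            train_ctrl = [row[ctrl_ids[i]] for i in ctrl_perm[:n_train_ctrl]]
            held_ctrl = [row[ctrl_ids[i]] for i in ctrl_perm[n_train_ctrl:]]
            cv_seed = int(rng.integers(0, 2**31))

            orth_rows: list[int] = []
            for pid in sampled_ids:
                avail = orth_rows_by_pos.get(pid, [])
                take = min(max_orthologs, len(avail))
                if take:
                    pick = rng.choice(len(avail), size=take, replace=False)
                    orth_rows.extend(avail[i] for i in sorted(pick))

            for condition in CONDITIONS:
                rows = [row[pid] for pid in sampled_ids] + train_ctrl
                eligible = [True] * len(rows)
                if condition == "with_orthologs":
                    rows = rows + orth_rows
                    eligible = eligible + [False] * len(orth_rows)
                fm = features.select(rows)
                roc, oof = cross_validate(
                    fm, k=k_folds, C=C, seed=cv_seed,
                    eligible_test=np.array(eligible),
                )
                model = train_svm(fm, C)
                held = held_pos + held_ctrl
                held_scores = model.decision(features.values[held])
                held_labels = features.labels[held]
                auc_true = roc_from_scores(held_labels, held_scores).auc
                tested = set(sampled_ids)
                positive = {
                    sid
                    for sid, i_local in zip(fm.sequence_ids, range(len(rows)))
                    if sid in tested and not np.isnan(oof[i_local]) and oof[i_local] > 0
                }
                records.append(
                    EvalRecord(
                        sample_size=size,
                        condition=condition,
                        replicate=rep,
                        auc_cv=roc.auc,
                        auc_true=auc_true,
                        tested_ids=tested,
                        positive_ids=positive,
                    )
                )
    return records


def compare_conditions(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Per-size summary: mean CV and true AUC per condition, paired
    signed-rank p-values, and the RMS error between CV and true AUC."""
    df = pd.DataFrame(
        {
            "size": [r.sample_size for r in records],
            "condition": [r.condition for r in records],
            "replicate": [r.replicate for r in records],
            "auc_cv": [r.auc_cv for r in records],
            "auc_true": [r.auc_true for r in records],
        }
    )
    rows = []
    for size, grp in df.groupby("size"):
        pivot_cv = grp.pivot(index="replicate", columns="condition", values="auc_cv")
        pivot_true = grp.pivot(index="replicate", columns="condition", values="auc_true")
        if pivot_cv.isna().any().any():
            raise ValueError(f"unpaired replicates at size {size}")
        entry = {"size": size}
        for cond in CONDITIONS:
            sub = grp[grp.condition == cond]
            entry[f"mean_auc_cv_{cond}"] = sub.auc_cv.mean()
            entry[f"mean_auc_true_{cond}"] = sub.auc_true.mean()
            entry[f"rms_error_{cond}"] = float(
                np.sqrt(np.mean((sub.auc_cv - sub.auc_true) ** 2))
            )
        entry["p_signed_rank_cv"] = signed_rank_test(
            pivot_cv["with_orthologs"], pivot_cv["dm_only"]
        )
        entry["p_signed_rank_true"] = signed_rank_test(
            pivot_true["with_orthologs"], pivot_true["dm_only"]
        )
        rows.append(entry)
    return pd.DataFrame(rows).set_index("size")


def recognition_and_concordance(
    records: Sequence[EvalRecord],
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recognized sequences (positively classified in >= ``threshold`` of
    the instances they were tested, inclusive) per (size, condition), and
    mean pairwise Jaccard concordance of positive sets between replicates."""
    recog_rows = []
    conc_rows = []
    groups: dict[tuple[int, str], list[EvalRecord]] = {}
    for r in records:
        groups.setdefault((r.sample_size, r.condition), []).append(r)
    for (size, cond), grp in sorted(groups.items()):
        tested: dict[str, int] = {}
        positive: dict[str, int] = {}
        for r in grp:
            for sid in r.tested_ids:
                tested[sid] = tested.get(sid, 0) + 1
            for sid in r.positive_ids:
                positive[sid] = positive.get(sid, 0) + 1
        recognized = sorted(
            sid for sid, nt in tested.items() if positive.get(sid, 0) / nt >= threshold
        )
        recog_rows.append(
            {
                "size": size,
                "condition": cond,
                "n_tested": len(tested),
                "n_recognized": len(recognized),
            }
        )
        jaccards, intersections = [], []
        for a in range(len(grp)):
            for b in range(a + 1, len(grp)):
                pa, pb = grp[a].positive_ids, grp[b].positive_ids
                union = pa | pb
                inter = pa & pb
                jaccards.append(len(inter) / len(union) if union else 1.0)
                intersections.append(len(inter))
        conc_rows.append(
            {
                "size": size,
                "condition": cond,
                "mean_jaccard": float(np.mean(jaccards)) if jaccards else np.nan,
                "mean_intersection": float(np.mean(intersections)) if intersections else np.nan,
            }
        )
    return pd.DataFrame(recog_rows), pd.DataFrame(conc_rows)


def plot_learning_curves(summary: pd.DataFrame, path) -> None:
    """Learning-curve and RMS-error panels from a compare_conditions table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for cond in CONDITIONS:
        ax1.plot(summary.index, summary[f"mean_auc_true_{cond}"], marker="o", label=cond)
        ax2.plot(summary.index, summary[f"rms_error_{cond}"], marker="o", label=cond)
    ax1.set_xlabel("training sample size")
    ax1.set_ylabel("mean true AUC")
    ax2.set_xlabel("training sample size")
    ax2.set_ylabel("RMS(auc_cv - auc_true)")
    ax1.legend()
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
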