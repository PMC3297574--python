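"""Feature construction and the class-cost-balanced linear max-margin model.

Sequences are represented by motif-match densities (matches per base pair,
one column per PWM).  A linear SVM minimizing

    1/2 ||w||^2 + sum_i C_class(i) * xi_i,   y_i (w.x_i + b) >= 1 - xi_i

is trained with per-class costs C_class = C * n / (2 * n_class), which gives
each class equal overall weight regardless of imbalance.  No feature scaling
is applied: densities are already length-normalized, and the max-margin
solution is deliberately left on that scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .motifs import (
    DEFAULT_P_THRESHOLD,
    Pwm,
    composition_background,
    count_per_bp,
    scan_sequence,
)
from .records import Interval, SequenceRecord

# Default soft-margin cost.  Match densities live on a ~1e-3 scale, so the
# non-degenerate regime of the primal (margin term comparable to the slack
# term) starts around C ~ 1e3; 1e4 sits comfortably inside it.
DEFAULT_C = 1e4


# ---------------------------------------------------------------------------
# Feature matrix


@dataclass
class FeatureMatrix:
    sequence_ids: list[str]
    motif_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    p_threshold: float = DEFAULT_P_THRESHOLD

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.sequence_ids), len(self.motif_ids)):
            raise ValueError("values shape does not match ids")
        if self.labels.shape[0] != len(self.sequence_ids):
            raise ValueError("labels length does not match rows")
        if np.any(self.values < 0):
            raise ValueError("match densities must be non-negative")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 / -1")

    def select(self, row_indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(row_indices)
        return FeatureMatrix(
            [self.sequence_ids[i] for i in idx],
            self.motif_ids,
            self.values[idx],
            self.labels[idx],
            self.background,
            self.p_threshold,
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.sequence_ids, columns=self.motif_ids)
        df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index_label="sequence_id")


def build_feature_matrix(
    seqs: Sequence[SequenceRecord],
    pwms: Sequence[Pwm],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    labels: Optional[Sequence[int]] = None,
    background: Optional[np.ndarray] = None,
) -> FeatureMatrix:
    """Entry (i, j) = matches of PWM j in sequence i per base pair.

    The scan background defaults to the mononucleotide composition of the
    whole input set, so every row is scored under the same null model.
    """
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in feature matrix input")
    bg = composition_background(seqs) if background is None else np.asarray(background, float)
    values = np.zeros((len(seqs), len(pwms)))
    for i, seq in enumerate(seqs):
        for j, pwm in enumerate(pwms):
            matches = scan_sequence(seq, pwm, p_threshold, background=bg)
            values[i, j] = count_per_bp(matches, seq)
    y = np.ones(len(seqs), dtype=int) if labels is None else np.asarray(labels, int)
    return FeatureMatrix(ids, [p.id for p in pwms], values, y, bg, p_threshold)


# ---------------------------------------------------------------------------
# Matched controls


def sample_matched_controls(
    positives: Sequence[SequenceRecord],
    genome: Sequence[SequenceRecord],
    exclusions: Sequence[Interval],
    n: int = 1000,
    seed: int = 0,
    gc_tolerance: float = 0.05,
    mask_tolerance: float = 0.05,
    max_draws: int = 10**6,
) -> list[SequenceRecord]:
    """Non-coding control regions matching the positives' length, GC and
    masked-fraction distributions by rejection sampling."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    chrom_lengths = np.array([len(c) for c in genome], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()
    by_chrom: dict[str, list[Interval]] = {}
    for iv in exclusions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    controls: list[SequenceRecord] = []
    draws = 0
    while len(controls) < n:
        if draws >= max_draws:
            rate = len(controls) / max(1, draws)
            raise ValueError(
                f"control acceptance rate {rate:.2e} too low after {draws} draws; "
                "relax gc/mask tolerances or enlarge the universe"
            )
        draws += 1
        template = positives[int(rng.integers(0, len(positives)))]
        length = len(template)
        ci = int(rng.choice(len(genome), p=chrom_p))
        chrom = genome[ci]
        if len(chrom) < length:
            continue
        start = int(rng.integers(0, len(chrom) - length + 1))
        iv = Interval(chrom.id, start, start + length)
        if any(iv.overlaps(x) for x in by_chrom.get(chrom.id, [])):
            continue
        cand = chrom.subsequence(start, start + length, sub_id=f"control_{len(controls):04d}")
        if cand.origin is None:
            cand.origin = iv
        if abs(cand.gc_fraction - template.gc_fraction) > gc_tolerance:
            continue
        if abs(cand.masked_fraction - template.masked_fraction) > mask_tolerance:
            continue
        controls.append(cand)
    return controls


# ---------------------------------------------------------------------------
# Linear SVM


@dataclass
class LinearModel:
    motif_ids: list[str]
    weights: np.ndarray
    bias: float
    C: float
    class_costs: tuple[float, float]  # (C+, C-)
    total_slack: float = 0.0
    n_margin_violations: int = 0
    objective: float = 0.0
    cutoff: Optional[float] = None
    background: Optional[np.ndarray] = None
    p_threshold: float = DEFAULT_P_THRESHOLD
    seed: Optional[int] = None

    def decision(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, float) @ self.weights + self.bias

    def to_json(self, path) -> None:
        doc = {
            "format": "cisclassify-model-v1",
            "motif_ids": self.motif_ids,
            "weights": [float(x) for x in self.weights],
            "bias": self.bias,
            "C": self.C,
            "class_costs": list(self.class_costs),
            "total_slack": self.total_slack,
            "n_margin_violations": self.n_margin_violations,
            "objective": self.objective,
            "cutoff": self.cutoff,
            "background": None if self.background is None else [float(x) for x in self.background],
            "p_threshold": self.p_threshold,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "cisclassify-model-v1":
            raise ValueError("unrecognized model file format")
        return cls(
            motif_ids=doc["motif_ids"],
            weights=np.array(doc["weights"]),
            bias=doc["bias"],
            C=doc["C"],
            class_costs=tuple(doc["class_costs"]),
            total_slack=doc["total_slack"],
            n_margin_violations=doc["n_margin_violations"],
            objective=doc["objective"],
            cutoff=doc["cutoff"],
            background=None if doc["background"] is None else np.array(doc["background"]),
            p_threshold=doc["p_threshold"],
            seed=doc["seed"],
        )


def class_costs(labels: np.ndarray, C: float) -> tuple[float, float]:
    """Balanced per-class costs: C_class = C * n / (2 * n_class), so that
    C+ * n+ = C- * n- (equal overall class weight)."""
    n = labels.size
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return C * n / (2 * n_pos), C * n / (2 * n_neg)


def train_svm(X: FeatureMatrix, C: float = DEFAULT_C) -> LinearModel:
    c_pos, c_neg = class_costs(X.labels, C)
    clf = SVC(kernel="linear", C=1.0, class_weight={1: c_pos, -1: c_neg}, tol=1e-6)
    clf.fit(X.values, X.labels)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    margins = X.labels * (X.values @ w + b)
    slack = np.maximum(0.0, 1.0 - margins)
    costs = np.where(X.labels == 1, c_pos, c_neg)
    return LinearModel(
        motif_ids=list(X.motif_ids),
        weights=w,
        bias=b,
        C=C,
        class_costs=(c_pos, c_neg),
        total_slack=float(slack.sum()),
        n_margin_violations=int(np.sum(slack > 1e-9)),
        objective=float(0.5 * w @ w + np.sum(costs * slack)),
        background=X.background,
        p_threshold=X.p_threshold,
    )


# ---------------------------------------------------------------------------
# ROC / cross-validation


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr_points: np.ndarray
    tpr_points: np.ndarray
    auc: float
    fold_aucs: list[float] = field(default_factory=list)


def roc_from_scores(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr_points=fpr, tpr_points=tpr, auc=auc)


def cross_validate(
    X: FeatureMatrix,
    k: int = 10,
    C: float = DEFAULT_C,
    seed: int = 0,
    fold_hook: Optional[Callable[[np.ndarray, np.ndarray, FeatureMatrix], tuple]] = None,
    eligible_test: Optional[np.ndarray] = None,
) -> tuple[RocCurve, np.ndarray]:
    """Stratified k-fold CV; out-of-fold decision values are pooled into one
    ROC.  ``fold_hook(train_idx, test_idx, X) -> (X_train_vals, X_test_vals)``
    lets fold-specific features (e.g. de novo motifs re-discovered on the
    training fold only) replace the precomputed ones.  ``eligible_test``
    marks rows allowed in validation folds (rows excluded from it are always
    kept in training, e.g. ortholog rows).  Returns (roc, oof_scores) where
    rows never tested carry NaN."""
    y = X.labels
    eligible = (
        np.ones(y.size, dtype=bool) if eligible_test is None else np.asarray(eligible_test, bool)
    )
    n_pos = int(np.sum(y[eligible] == 1))
    n_neg = int(np.sum(y[eligible] == -1))
    if k > min(n_pos, n_neg):
        raise ValueError(f"k={k} exceeds smallest class size {min(n_pos, n_neg)}")
    elig_idx = np.nonzero(eligible)[0]
    always_train = np.nonzero(~eligible)[0]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(y.size, np.nan)
    fold_aucs = []
    for sub_train, sub_test in skf.split(np.zeros(elig_idx.size), y[elig_idx]):
        train_idx = np.concatenate([elig_idx[sub_train], always_train])
        test_idx = elig_idx[sub_test]
        if fold_hook is not None:
            train_vals, test_vals = fold_hook(train_idx, test_idx, X)
            fm = FeatureMatrix(
                [X.sequence_ids[i] for i in train_idx],
                list(range(train_vals.shape[1])) if train_vals.shape[1] != len(X.motif_ids)
                else X.motif_ids,
                train_vals,
                y[train_idx],
                X.background,
                X.p_threshold,
            )
            model = train_svm(fm, C)
            scores = test_vals @ model.weights + model.bias
        else:
            model = train_svm(X.select(train_idx), C)
            scores = model.decision(X.values[test_idx])
        oof[test_idx] = scores
        if len(set(y[test_idx])) == 2:
            fold_aucs.append(roc_from_scores(y[test_idx], scores).auc)
    tested = ~np.isnan(oof)
    roc = roc_from_scores(y[tested], oof[tested])
    roc.fold_aucs = fold_aucs
    return roc, oof


# ---------------------------------------------------------------------------
# Motif ranking


@dataclass
class RankedMotif:
    motif_id: str
    median_rank: float
    mean_rank: float
    weight_share: float
    sign: str  # '+', '-', '0'


def _partition_splits(y: np.ndarray, n_partitions: int, train_fraction: float, seed: int):
    sss = StratifiedShuffleSplit(
        n_splits=n_partitions, train_size=train_fraction, random_state=seed
    )
    return sss.split(np.zeros(y.size), y)


def rank_motifs(
    X: FeatureMatrix,
    C: float = DEFAULT_C,
    n_partitions: int = 100,
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> list[RankedMotif]:
    """Features ranked by |w_j| within each random training partition, then
    ordered by median rank (ties: mean rank, then library order)."""
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    m = len(X.motif_ids)
    ranks = np.zeros((n_partitions, m))
    signs = np.zeros((n_partitions, m))
    for p, (train_idx, _) in enumerate(_partition_splits(X.labels, n_partitions, train_fraction, seed)):
        model = train_svm(X.select(train_idx), C)
        order = np.argsort(-np.abs(model.weights), kind="stable")
        r = np.empty(m)
        r[order] = np.arange(1, m + 1)
        ranks[p] = r
        signs[p] = np.sign(model.weights)
    full_model = train_svm(X, C)
    total = np.abs(full_model.weights).sum()
    shares = np.abs(full_model.weights) / total if total > 0 else np.zeros(m)
    medians = np.median(ranks, axis=0)
    means = ranks.mean(axis=0)
    out = []
    for j in np.lexsort((np.arange(m), means, medians)):
        s = signs[:, j].sum()
        sign = "+" if s > 0 else ("-" if s < 0 else "0")
        if shares[j] == 0 and np.all(signs[:, j] == 0):
            sign = "0"
        out.append(
            RankedMotif(
                motif_id=X.motif_ids[j],
                median_rank=float(medians[j]),
                mean_rank=float(means[j]),
                weight_share=float(shares[j]),
                sign=sign,
            )
        )
    return out


def weight_concentration(weights: np.ndarray, fraction: float = 0.5) -> int:
    """Smallest number of top-|w| features holding more than ``fraction`` of
    sum |w| (so weights (5,3,1,1) need the top 2 to pass one half)."""
    mags = np.sort(np.abs(np.asarray(weights, float)))[::-1]
    total = mags.sum()
    if total == 0:
        return 0
    cum = np.cumsum(mags) / total
    return int(np.searchsorted(cum, fraction, side="right") + 1)


# ---------------------------------------------------------------------------
# FPR cutoff calibration


def calibrate_fpr_cutoff(
    X: FeatureMatrix,
    C: float = DEFAULT_C,
    fpr: float = 0.05,
    n_partitions: int = 100,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[float, LinearModel]:
    """Decision-value cutoff at which at most ``fpr`` of pooled held-out
    control scores (across random partitions) fall above; returned with the
    model trained on the full data (cutoff stored on it).

    The cutoff is deployed with the full-data model, so the calibration
    models must match its decision-value scale: partitions hold out 10% by
    default (cross-fitting), because at a 2/3 training fraction the smaller
    partition models systematically score controls higher than the deployed
    model and the realized false-positive rate undershoots the target."""
    if not (0 < fpr <= 1):
        raise ValueError("fpr must lie in (0, 1]")
    pooled = []
    for train_idx, test_idx in _partition_splits(X.labels, n_partitions, train_fraction, seed):
        model = train_svm(X.select(train_idx), C)
        controls = test_idx[X.labels[test_idx] == -1]
        if controls.size:
            pooled.append(model.decision(X.values[controls]))
    if not pooled:
        raise ValueError("no held-out controls available for calibration")
    pool = np.concatenate(pooled)
    if fpr >= 1.0:
        cutoff = float(pool.min())
    else:
        cutoff = float(np.quantile(pool, 1 - fpr, method="higher"))
    full_model = train_svm(X, C)
    full_model.cutoff = cutoff
    full_model.seed = seed
    return cutoff, full_model
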