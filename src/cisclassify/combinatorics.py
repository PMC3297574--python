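"""TFBS composition analysis across an enhancer set.

Enhancers are reduced to a boolean presence matrix over motif *classes*
(each class is a set of PWMs and/or IUPAC consensus patterns bound by one
TF family).  The matrix supports uniqueness counting, shared-subset curves
(the maximum fraction of enhancers sharing any N classes), and hierarchical
clustering with either binary (Jaccard) or Euclidean distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .motifs import DEFAULT_P_THRESHOLD, Pwm, composition_background, consensus_match, scan_sequence
from .records import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class MotifClass:
    """A named TF class: PWM ids from a library plus optional IUPAC
    consensus patterns (used for matrices built from too few sites to scan
    reliably — these classes are flagged lower-confidence)."""

    name: str
    pwm_ids: list[str] = field(default_factory=list)
    patterns: list[str] = field(default_factory=list)
    lower_confidence: bool = False


def default_motif_classes() -> list[MotifClass]:
    """The 11 founder-cell-relevant TF classes: six defined by TRANSFAC
    matrix identifiers and five literature factors realized as IUPAC
    consensus patterns (lower confidence)."""
    return [
        MotifClass("POUHD", ["V$OCT_01", "V$POU1F1_Q6", "V$OCT4_02"]),
        MotifClass("Tbx", ["V$TBX5_01", "I$BYN_Q6"]),
        MotifClass("Myb", ["V$MYB_Q6"]),
        MotifClass("Fkh", ["V$FOXO3_01", "V$FOXO1_Q5", "V$FREAC2_01"]),
        MotifClass("HD", ["I$ABDA_Q6", "V$CDX5_Q5", "V$IFP_03", "V$PAX4_02"]),
        MotifClass("Mef2", ["V$AMEF2_Q6", "V$HMEF2_Q6"]),
        MotifClass("Tcf", patterns=["CTTTGWW"], lower_confidence=True),
        MotifClass("Mad", patterns=["GCCGNCGC"], lower_confidence=True),
        MotifClass("Ets", patterns=["MGGAWR"], lower_confidence=True),
        MotifClass("Twi", patterns=["CAYATG"], lower_confidence=True),
        MotifClass("Tin", patterns=["TYAAGTG"], lower_confidence=True),
    ]


@dataclass
class CompositionMatrix:
    enhancer_ids: list[str]
    class_ids: list[str]
    presence: np.ndarray  # bool, enhancers x classes

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.enhancer_ids), len(self.class_ids)):
            raise ValueError("presence shape does not match ids")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.presence.astype(int), index=self.enhancer_ids, columns=self.class_ids
        ).to_csv(path, sep="\t", index_label="enhancer_id")


def composition_matrix(
    enhancers: Sequence[SequenceRecord],
    classes: Sequence[MotifClass],
    pwms: Sequence[Pwm] = (),
    p_threshold: float = DEFAULT_P_THRESHOLD,
    background: Optional[np.ndarray] = None,
) -> CompositionMatrix:
    """presence(i, c) is true iff enhancer i has >= 1 match to >= 1 PWM or
    pattern of class c."""
    by_id = {p.id: p for p in pwms}
    for cls in classes:
        missing = [pid for pid in cls.pwm_ids if pid not in by_id]
        if missing:
            raise ValueError(f"class {cls.name!r}: unknown PWM ids {missing}")
    bg = composition_background(enhancers) if background is None else np.asarray(background)
    presence = np.zeros((len(enhancers), len(classes)), dtype=bool)
    for i, enh in enumerate(enhancers):
        for c, cls in enumerate(classes):
            hit = any(
                scan_sequence(enh, by_id[pid], p_threshold, background=bg)
                for pid in cls.pwm_ids
            ) or any(consensus_match(enh, pat) for pat in cls.patterns)
            presence[i, c] = hit
    return CompositionMatrix([e.id for e in enhancers], [c.name for c in classes], presence)


def unique_combination_count(m: CompositionMatrix) -> int:
    """Number of distinct presence rows (distinct TFBS-class combinations)."""
    return len({tuple(row) for row in m.presence})


def max_shared_fraction(m: CompositionMatrix, n: int) -> float:
    """Max over all size-n class subsets of the fraction of enhancers that
    possess every class in the subset (exact enumeration)."""
    n_classes = len(m.class_ids)
    if not (1 <= n <= n_classes):
        raise ValueError(f"N must lie in [1, {n_classes}]")
    if len(m.enhancer_ids) == 0:
        return 0.0
    best = 0.0
    for subset in combinations(range(n_classes), n):
        frac = float(m.presence[:, subset].all(axis=1).mean())
        best = max(best, frac)
    return best


def binary_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mismatched features over features present in either row; joint
    absences ignored.  An all-absent row is at distance 1 from any non-empty
    row and 0 from another all-absent row."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.sum(a | b)
    if union == 0:
        return 0.0
    return float(np.sum(a != b) / union)


def _distance_matrix(rows: np.ndarray, distance: str) -> np.ndarray:
    n = rows.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if distance == "binary_jaccard":
                d[i, j] = d[j, i] = binary_distance(rows[i], rows[j])
            elif distance == "euclidean":
                d[i, j] = d[j, i] = float(np.linalg.norm(rows[i].astype(float) - rows[j].astype(float)))
            else:
                raise ValueError(f"unknown distance {distance!r}")
    return d


def cluster_rows(
    matrix: np.ndarray,
    distance: str = "binary_jaccard",
    method: str = "ward",
) -> np.ndarray:
    """Agglomerative clustering; returns the merge list (scipy linkage
    matrix: [left, right, height, size] per merge).

    Ward linkage on non-Euclidean binary distances is mathematically impure
    but matches common statistical-package behavior; a warning is logged.
    """
    rows = np.asarray(matrix)
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if method not in ("ward", "average"):
        raise ValueError(f"unknown linkage {method!r}")
    d = _distance_matrix(rows, distance)
    if method == "ward" and distance == "binary_jaccard":
        logger.warning("Ward linkage applied to binary distances as-is (non-Euclidean)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return linkage(squareform(d, checks=False), method=method)


def linkage_to_newick(merge: np.ndarray, labels: Sequence[str]) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    tree = to_tree(merge)

    def render(node, parent_height):
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
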