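"""Position weight matrices: parsing, log-odds scanning, and enrichment.

A motif match is declared wherever the log-odds score of a window reaches a
significance gate: an exact tail probability of the score under the
background mononucleotide model, computed by position-wise convolution of
the per-column score distribution.  The gate defaults to p <= 1e-4 per
position, evaluated on both strands.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .records import SequenceRecord, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {c: i for i, c in enumerate(BASES)}

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_P_THRESHOLD = 1e-4


# ---------------------------------------------------------------------------
# PWM


@dataclass
class Pwm:
    """Position probability matrix (columns A, C, G, T)."""

    id: str
    probs: np.ndarray
    name: str = ""
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    source: str = "library"  # library | de_novo | literature

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM {self.id!r}: probs must be width x 4")
        if np.any(self.probs <= 0):
            raise ValueError(f"PWM {self.id!r}: zero/negative entries after regularization")
        rows = self.probs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError(f"PWM {self.id!r}: rows do not sum to 1")
        if not self.name:
            self.name = self.id

    @classmethod
    def from_counts(
        cls,
        id: str,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        **kw,
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        reg = counts + pseudocount
        probs = reg / reg.sum(axis=1, keepdims=True)
        return cls(id=id, probs=probs, pseudocount=pseudocount, **kw)

    @classmethod
    def from_probs(
        cls,
        id: str,
        probs: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        **kw,
    ) -> "Pwm":
        """Regularize only when a row has a (near-)zero entry, so that
        already-regular matrices pass through unchanged (round-trip safety)."""
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < 1e-12):
            probs = (probs + pseudocount) / (probs + pseudocount).sum(axis=1, keepdims=True)
        else:
            probs = probs / probs.sum(axis=1, keepdims=True)
        return cls(id=id, probs=probs, pseudocount=pseudocount, **kw)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self, background: Optional[np.ndarray] = None) -> float:
        """Total information content in bits (sum over columns of KL to background)."""
        bg = uniform_background() if background is None else np.asarray(background, float)
        return float(np.sum(self.probs * np.log2(self.probs / bg[None, :])))

    def sample(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(4, p=row / row.sum()) for row in self.probs]
        return "".join(BASES[i] for i in cols)

    def digest(self) -> str:
        return hashlib.sha1(np.round(self.probs, 12).tobytes()).hexdigest()[:16]


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def composition_background(seqs: Union[SequenceRecord, Iterable[SequenceRecord]]) -> np.ndarray:
    """Mononucleotide composition of a sequence set (N ignored), floored at 1%."""
    if isinstance(seqs, SequenceRecord):
        seqs = [seqs]
    counts = np.zeros(4)
    for rec in seqs:
        up = rec.residues.upper()
        for i, c in enumerate(BASES):
            counts[i] += up.count(c)
    if counts.sum() == 0:
        return uniform_background()
    bg = counts / counts.sum()
    bg = np.maximum(bg, 0.01)
    return bg / bg.sum()


def log_odds(pwm: Pwm, background: np.ndarray) -> np.ndarray:
    """Per-position log2(prob / background) scoring table in bits."""
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    return np.log2(pwm.probs / background[None, :])


def reverse_complement_table(table: np.ndarray) -> np.ndarray:
    """Scoring table for the reverse strand: reverse rows, swap A<->T, C<->G."""
    return table[::-1, [3, 2, 1, 0]]


# ---------------------------------------------------------------------------
# Exact score distribution


class ScoreDistribution:
    """Exact distribution of the log-odds score of a random background word.

    Built by position-wise convolution over the motif columns.  Partial sums
    are kept exact (merged on equality) while their number stays moderate;
    beyond that they are binned at 1e-3 bits, well inside the 0.01-bit cap.
    """

    _MAX_EXACT = 300_000
    _BIN = 1e-3

    def __init__(self, table: np.ndarray, background: np.ndarray):
        values = np.zeros(1)
        probs = np.ones(1)
        for row in table:
            values = (values[:, None] + row[None, :]).ravel()
            probs = (probs[:, None] * background[None, :]).ravel()
            if values.size > self._MAX_EXACT:
                values = np.round(values / self._BIN) * self._BIN
            keys = np.round(values, 9)
            _, first, inverse = np.unique(keys, return_index=True, return_inverse=True)
            merged = np.zeros(first.size)
            np.add.at(merged, inverse, probs)
            values, probs = values[first], merged
        order = np.argsort(values)
        self.values = values[order]
        self.probs = probs[order]
        # survival[i] = P(S >= values[i])
        self._survival = np.cumsum(self.probs[::-1])[::-1]

    #: scores closer than this (in bits) are treated as equal
    TOL = 1e-6

    def sf(self, score: float) -> float:
        """P(S >= score) with a small tolerance for float summation order."""
        idx = np.searchsorted(self.values, score - self.TOL, side="left")
        if idx >= self.values.size:
            return 0.0
        return float(min(1.0, self._survival[idx]))

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest attainable score with sf(score) <= p_threshold (inf if none)."""
        mask = self._survival <= p_threshold + 1e-15
        if not mask.any():
            return math.inf
        return float(self.values[np.argmax(mask)])

    @property
    def min_score(self) -> float:
        return float(self.values[0])


_DIST_CACHE: dict[tuple, ScoreDistribution] = {}


def score_distribution(pwm: Pwm, background: np.ndarray) -> ScoreDistribution:
    key = (pwm.id, pwm.digest(), tuple(np.round(background, 12)))
    if key not in _DIST_CACHE:
        if len(_DIST_CACHE) > 4096:
            _DIST_CACHE.clear()
        _DIST_CACHE[key] = ScoreDistribution(log_odds(pwm, background), np.asarray(background))
    return _DIST_CACHE[key]


def score_pvalue(pwm: Pwm, score: float, background: np.ndarray) -> float:
    """Exact tail probability P(S >= score) for a background word of motif width."""
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    return score_distribution(pwm, np.asarray(background, float)).sf(score)


# ---------------------------------------------------------------------------
# Scanning


@dataclass
class MotifMatch:
    pwm_id: str
    sequence_id: str
    offset: int
    strand: str
    score: Optional[float] = None
    p_value: Optional[float] = None
    width: int = 0


def _encode(residues: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for c, i in _BASE_INDEX.items():
        table[ord(c)] = i
        table[ord(c.lower())] = i
    return table[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def _window_scores(code: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; -inf where the window touches an N."""
    w = table.shape[0]
    n = code.size - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.hstack([table, np.full((w, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    return padded[np.arange(w)[None, :], windows].sum(axis=1)


def scan_sequence(
    seq: SequenceRecord,
    pwm: Pwm,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_strands: bool = True,
    background: Optional[np.ndarray] = None,
) -> list[MotifMatch]:
    """All offsets/strands whose score tail probability is <= p_threshold.

    Overlapping matches are all reported; windows containing N are skipped;
    a sequence shorter than the motif yields an empty list.
    """
    w = pwm.width
    if len(seq) < w:
        return []
    bg = composition_background(seq) if background is None else np.asarray(background, float)
    table = log_odds(pwm, bg)
    dist = score_distribution(pwm, bg)
    cutoff = dist.score_threshold(p_threshold)
    if not math.isfinite(cutoff):
        return []
    code = _encode(seq.residues)
    matches = []
    fwd = _window_scores(code, table)
    strands = [("+", fwd)]
    if both_strands:
        strands.append(("-", _window_scores(code, reverse_complement_table(table))))
    hits: list[tuple[int, str, float]] = []
    for strand, scores in strands:
        idx = np.nonzero(scores >= cutoff - ScoreDistribution.TOL)[0]
        for i in idx:
            hits.append((int(i), strand, float(scores[i])))
    hits.sort(key=lambda h: (h[0], h[1]))
    for offset, strand, score in hits:
        matches.append(
            MotifMatch(
                pwm_id=pwm.id,
                sequence_id=seq.id,
                offset=offset,
                strand=strand,
                score=score,
                p_value=dist.sf(score),
                width=w,
            )
        )
    return matches


def count_per_bp(matches: Sequence[MotifMatch], seq: SequenceRecord) -> float:
    """Match density: number of putative TFBSs per base pair."""
    if len(seq) == 0:
        raise ValueError("zero-length sequence")
    for m in matches:
        if m.sequence_id != seq.id:
            raise ValueError(f"match {m.pwm_id}@{m.offset} belongs to {m.sequence_id!r}")
    return len(matches) / len(seq)


def consensus_match(seq: SequenceRecord, iupac_pattern: str) -> list[MotifMatch]:
    """Exact IUPAC pattern matches on both strands (no score / p-value)."""
    pattern = iupac_pattern.upper()
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC letters: {sorted(bad)}")
    w = len(pattern)
    residues = seq.residues.upper()
    rc_pattern = pattern.translate(_IUPAC_COMPLEMENT)[::-1]
    matches = []
    for offset in range(len(residues) - w + 1):
        word = residues[offset : offset + w]
        for strand, pat in (("+", pattern), ("-", rc_pattern)):
            if all(c in IUPAC_CODES[p] for c, p in zip(word, pat) if True):
                if "N" in word:
                    continue
                matches.append(
                    MotifMatch(
                        pwm_id=iupac_pattern,
                        sequence_id=seq.id,
                        offset=offset,
                        strand=strand,
                        width=w,
                    )
                )
    return matches


# ---------------------------------------------------------------------------
# Over-representation statistics


@dataclass
class TestResult:
    motif_id: str
    count_query: int
    count_background: int
    n_query: int
    n_background: int
    p_value: float
    q_value: float = field(default=np.nan)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def fisher_overrepresentation(
    query: Sequence[SequenceRecord],
    background: Sequence[SequenceRecord],
    pwms: Sequence[Pwm],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    scan_background: Optional[np.ndarray] = None,
) -> list[TestResult]:
    """One-sided (enrichment) Fisher's exact test per motif, BH-adjusted.

    The 2x2 unit is per-sequence presence/absence of >= 1 match; match calls
    use a shared background computed from the union of both sets unless
    overridden.
    """
    if not query or not background:
        raise ValueError("query and background sets must be non-empty")
    if not pwms:
        return []
    bg = (
        composition_background(list(query) + list(background))
        if scan_background is None
        else np.asarray(scan_background, float)
    )
    results = []
    for pwm in pwms:
        hit_q = sum(
            bool(scan_sequence(s, pwm, p_threshold, background=bg)) for s in query
        )
        hit_b = sum(
            bool(scan_sequence(s, pwm, p_threshold, background=bg)) for s in background
        )
        table = [[hit_q, len(query) - hit_q], [hit_b, len(background) - hit_b]]
        _, p = fisher_exact(table, alternative="greater")
        results.append(
            TestResult(
                motif_id=pwm.id,
                count_query=hit_q,
                count_background=hit_b,
                n_query=len(query),
                n_background=len(background),
                p_value=float(p),
            )
        )
    q_values = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, q_values):
        r.q_value = float(q)
    return results


# ---------------------------------------------------------------------------
# Motif file formats


def parse_motif_library(path, dialect: str) -> list[Pwm]:
    if dialect == "meme_minimal":
        return _parse_meme(path)
    if dialect == "transfac_matrix":
        return _parse_transfac(path)
    raise ValueError(f"unknown motif dialect: {dialect!r}")


def _parse_meme(path) -> list[Pwm]:
    pwms = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            name = parts[2] if len(parts) > 2 else motif_id
            width = None
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise ValueError(
                        f"line {j + 1}: motif {motif_id!r} has no probability matrix"
                    )
                j += 1
            if j >= len(lines):
                raise ValueError(f"line {i + 1}: motif {motif_id!r} has no matrix")
            m = re.search(r"w=\s*(\d+)", lines[j])
            if not m:
                raise ValueError(f"line {j + 1}: motif {motif_id!r} missing width")
            width = int(m.group(1))
            rows = []
            for k in range(width):
                row_line = lines[j + 1 + k].split()
                if len(row_line) != 4:
                    raise ValueError(
                        f"line {j + 2 + k}: motif {motif_id!r} malformed matrix row"
                    )
                rows.append([float(x) for x in row_line])
            pwms.append(Pwm.from_probs(motif_id, np.array(rows), name=name))
            i = j + 1 + width
        else:
            i += 1
    return pwms


def write_meme(pwms: Sequence[Pwm], path, background: Optional[np.ndarray] = None) -> None:
    bg = uniform_background() if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {bg[i]:.6f}" for i, c in enumerate(BASES)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.id} {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{x:.10f}" for x in row) + "\n")
            fh.write("\n")


def _parse_transfac(path) -> list[Pwm]:
    pwms = []
    with open(path) as fh:
        lines = fh.readlines()
    motif_id: Optional[str] = None
    name = ""
    rows: list[list[float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.startswith("ID"):
            motif_id = line.split(None, 1)[1].strip()
            rows = []
            name = motif_id
        elif line.startswith("NA"):
            name = line.split(None, 1)[1].strip()
        elif line.startswith("P0") or line.startswith("PO"):
            continue
        elif re.match(r"^\d\d\s", line):
            parts = line.split()
            if motif_id is None:
                raise ValueError(f"line {lineno}: matrix row before ID")
            if len(parts) < 5:
                raise ValueError(
                    f"line {lineno}: motif {motif_id!r} malformed count row"
                )
            rows.append([float(x) for x in parts[1:5]])
        elif line.startswith("//"):
            if motif_id is not None:
                if not rows:
                    raise ValueError(f"line {lineno}: motif {motif_id!r} has no rows")
                pwms.append(Pwm.from_counts(motif_id, np.array(rows), name=name))
            motif_id, rows, name = None, [], ""
    if motif_id is not None:
        if not rows:
            raise ValueError(f"motif {motif_id!r} has no rows at end of file")
        pwms.append(Pwm.from_counts(motif_id, np.array(rows), name=name))
    return pwms


def write_transfac(pwms: Sequence[Pwm], path, nsites: int = 100) -> None:
    """Write probabilities scaled to pseudo-counts (nsites per column)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.id}\nNA {pwm.name}\nP0      A      C      G      T\n")
            for i, row in enumerate(pwm.probs, start=1):
                counts = row * nsites
                consensus = BASES[int(np.argmax(row))]
                fh.write(
                    f"{i:02d}  {counts[0]:.4f}  {counts[1]:.4f}  {counts[2]:.4f}  "
                    f"{counts[3]:.4f}  {consensus}\n"
                )
            fh.write("XX\n//\n")


def matches_to_bed(matches: Sequence[MotifMatch], path) -> None:
    """Matches as BED6; score column is bits x 100, integer-truncated."""
    with open(path, "w") as fh:
        for m in matches:
            score = int((m.score or 0.0) * 100)
            fh.write(
                f"{m.sequence_id}\t{m.offset}\t{m.offset + m.width}\t"
                f"{m.pwm_id}\t{score}\t{m.strand}\n"
            )
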