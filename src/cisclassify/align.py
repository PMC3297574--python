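"""Global affine-gap alignment and the percent-identity metric.

Scoring: match +1, mismatch -1, gap open -5 (cost of the first gap column),
gap extend -1 per additional column.  Identity is matches / aligned columns,
with gap columns counted in the denominator.

Among co-optimal alignments the one maximizing the number of matches, then
minimizing the number of aligned columns, is chosen — this makes the metric
a deterministic function of the two sequences and symmetric by construction
of the scoring scheme.  The DP packs (score, matches, -columns) into one
int64 so the lexicographic optimum is a plain numeric maximum.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .records import SequenceRecord

MATCH = 1
MISMATCH = -1
GAP_OPEN = 5  # positive penalties
GAP_EXTEND = 1

_NEG = np.int64(-(2**62))


@njit(cache=True)
def _gotoh_packed(a: np.ndarray, b: np.ndarray) -> np.int64:  # pragma: no cover
    m, n = a.size, b.size
    cmax = m + n
    mmax = min(m, n)
    B = np.int64(cmax + 1)
    A = np.int64((mmax + 1)) * B + np.int64(cmax + 1)

    open_m = -GAP_OPEN * A - 1  # one gap column opened
    ext = -GAP_EXTEND * A - 1

    M = np.full(n + 1, _NEG, dtype=np.int64)
    X = np.full(n + 1, _NEG, dtype=np.int64)  # gap in b (consumes a)
    Y = np.full(n + 1, _NEG, dtype=np.int64)  # gap in a (consumes b)
    M[0] = 0
    if n >= 1:
        Y[1] = open_m
    for j in range(2, n + 1):
        Y[j] = Y[j - 1] + ext

    Mp = np.empty(n + 1, dtype=np.int64)
    Xp = np.empty(n + 1, dtype=np.int64)
    Yp = np.empty(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        Mp[:] = M
        Xp[:] = X
        Yp[:] = Y
        M[0] = _NEG
        Y[0] = _NEG
        X[0] = open_m if i == 1 else Xp[0] + ext
        for j in range(1, n + 1):
            eq = a[i - 1] == b[j - 1]
            step = (MATCH * A + B - 1) if eq else (MISMATCH * A - 1)
            best_prev = Mp[j - 1]
            if Xp[j - 1] > best_prev:
                best_prev = Xp[j - 1]
            if Yp[j - 1] > best_prev:
                best_prev = Yp[j - 1]
            M[j] = best_prev + step if best_prev > _NEG else _NEG

            xo = Mp[j] if Mp[j] > Yp[j] else Yp[j]
            x1 = xo + open_m if xo > _NEG else _NEG
            x2 = Xp[j] + ext if Xp[j] > _NEG else _NEG
            X[j] = x1 if x1 > x2 else x2

            yo = M[j - 1] if M[j - 1] > X[j - 1] else X[j - 1]
            y1 = yo + open_m if yo > _NEG else _NEG
            y2 = Y[j - 1] + ext if Y[j - 1] > _NEG else _NEG
            Y[j] = y1 if y1 > y2 else y2

    out = M[n]
    if X[n] > out:
        out = X[n]
    if Y[n] > out:
        out = Y[n]
    return out


def _encode_seq(residues: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        table[ord(c)] = i
        table[ord(c.lower())] = i
    return table[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def align_stats(a_res: str, b_res: str) -> tuple[int, int, int]:
    """(score, matches, aligned_columns) of the optimal global alignment."""
    a = _encode_seq(a_res)
    b = _encode_seq(b_res)
    m, n = a.size, b.size
    cmax = m + n
    mmax = min(m, n)
    B = cmax + 1
    A = (mmax + 1) * B + (cmax + 1)
    packed = int(_gotoh_packed(a, b))
    score = (packed + cmax) // A
    r = packed - score * A
    matches = (r + cmax) // B
    columns = matches * B - r
    return score, matches, columns


def percent_identity(a: SequenceRecord, b: SequenceRecord) -> tuple[float, int]:
    """Percent identity over the global alignment (gap columns in the
    denominator); returns (identity in [0, 100], aligned columns)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty sequences")
    _, matches, columns = align_stats(a.residues, b.residues)
    return 100.0 * matches / columns, columns
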