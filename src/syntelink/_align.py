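"""Global-alignment kernel used for percent-identity computation.

Scoring: match +1, mismatch -1, gap open -2 (charged on the first base of a
gap), gap extension -1 per additional base. Because several alignments can
share the optimal score while differing in their number of matched columns,
the DP optimises lexicographically: maximal score, then maximal matches,
then maximal aligned (non-gap) columns. This makes the reported match count
— and therefore the identity fraction — a well-defined function of the two
sequences.

The three objectives are packed into a single int64 per cell
(score * 2^40 + matches * 2^20 + aligned), so the lexicographic maximum is
the numeric maximum; field widths allow sequences up to ~1 Mb.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MATCH = 1
_MISMATCH = -1
_GAP_OPEN = -2  # first base of a gap
_GAP_EXTEND = -1  # each further base

_SHIFT_SCORE = 40
_SHIFT_MATCH = 20
_ONE_SCORE = np.int64(1) << _SHIFT_SCORE
_ONE_MATCH = np.int64(1) << _SHIFT_MATCH
_NEG_INF = np.int64(-(1 << 62))

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (A/C/G/T -> 0..3, other -> 4+)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _CODE[raw].copy()
    # distinct non-ACGT characters must not match each other
    ambiguous = out == 4
    out[ambiguous] = raw[ambiguous] + 8
    return out


@njit(cache=True)
def _align_packed(a: np.ndarray, b: np.ndarray) -> np.int64:  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    open_pen = np.int64(-_GAP_OPEN) * _ONE_SCORE
    ext_pen = np.int64(-_GAP_EXTEND) * _ONE_SCORE

    # rolling rows of the three-state DP: M ends in a substitution column,
    # X ends in a gap in b (a-char unmatched), Y ends in a gap in a
    M_prev = np.full(m + 1, _NEG_INF, dtype=np.int64)
    X_prev = np.full(m + 1, _NEG_INF, dtype=np.int64)
    Y_prev = np.full(m + 1, _NEG_INF, dtype=np.int64)
    M_cur = np.full(m + 1, _NEG_INF, dtype=np.int64)
    X_cur = np.full(m + 1, _NEG_INF, dtype=np.int64)
    Y_cur = np.full(m + 1, _NEG_INF, dtype=np.int64)

    M_prev[0] = 0
    for j in range(1, m + 1):
        if j == 1:
            Y_prev[j] = -open_pen
        else:
            Y_prev[j] = Y_prev[j - 1] - ext_pen

    for i in range(1, n + 1):
        M_cur[0] = _NEG_INF
        Y_cur[0] = _NEG_INF
        if i == 1:
            X_cur[0] = -open_pen
        else:
            X_cur[0] = X_prev[0] - ext_pen
        ai = a[i - 1]
        for j in range(1, m + 1):
            # substitution
            best = M_prev[j - 1]
            if X_prev[j - 1] > best:
                best = X_prev[j - 1]
            if Y_prev[j - 1] > best:
                best = Y_prev[j - 1]
            if best > _NEG_INF:
                if ai == b[j - 1]:
                    M_cur[j] = best + _ONE_SCORE + _ONE_MATCH + 1
                else:
                    M_cur[j] = best - _ONE_SCORE + 1
            else:
                M_cur[j] = _NEG_INF
            # gap in b (consume a[i-1])
            best = M_prev[j] - open_pen
            if X_prev[j] - ext_pen > best:
                best = X_prev[j] - ext_pen
            if Y_prev[j] - open_pen > best:
                best = Y_prev[j] - open_pen
            X_cur[j] = best
            # gap in a (consume b[j-1])
            best = M_cur[j - 1] - open_pen
            if X_cur[j - 1] - open_pen > best:
                best = X_cur[j - 1] - open_pen
            if Y_cur[j - 1] - ext_pen > best:
                best = Y_cur[j - 1] - ext_pen
            Y_cur[j] = best
        M_prev, M_cur = M_cur, M_prev
        X_prev, X_cur = X_cur, X_prev
        Y_prev, Y_cur = Y_cur, Y_prev

    best = M_prev[m]
    if X_prev[m] > best:
        best = X_prev[m]
    if Y_prev[m] > best:
        best = Y_prev[m]
    return best


def global_alignment_stats(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Optimal global alignment of two sequences.

    Returns ``(score, matches, aligned_columns)`` where matches is maximal
    among optimal-score alignments and aligned_columns (substitution
    columns) maximal among those.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    packed = int(_align_packed(encode(seq_a), encode(seq_b)))
    score = packed >> _SHIFT_SCORE
    matches = (packed >> _SHIFT_MATCH) & ((1 << 20) - 1)
    aligned = packed & ((1 << 20) - 1)
    return score, matches, aligned
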