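"""Banded global pairwise alignment for collinear, near-identical sequences.

Plastomes of one species complex differ by sparse SNPs and short InDels, so a
global (Needleman-Wunsch) alignment restricted to a diagonal band around the
main diagonal is exact in practice and linear-time in sequence length.  The
default scoring is match +1, mismatch -2, gap open -5, gap extend -1 (a gap of
length L costs 5 + L), with a band half-width of 200 columns.

The dynamic program runs in a numba-compiled kernel; the band follows the
straight line between the alignment corners so moderately different lengths
stay centred.  If the optimal path cannot reach the final corner inside the
band a :class:`CollinearityError` is raised: the inputs are then not
collinear enough for this aligner and an externally computed alignment
should be supplied instead.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["CollinearityError", "banded_align", "DEFAULT_BAND"]

DEFAULT_BAND = 200
_NEG = -(1 << 40)


class CollinearityError(ValueError):
    """Sequences too divergent/shifted for banded collinear alignment."""


@njit(cache=True)
def _banded_affine_kernel(a, b, band, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.size
    m = b.size
    W = 2 * band + 1
    M_prev = np.full(W, _NEG, np.int64)
    X_prev = np.full(W, _NEG, np.int64)
    Y_prev = np.full(W, _NEG, np.int64)
    M_cur = np.full(W, _NEG, np.int64)
    X_cur = np.full(W, _NEG, np.int64)
    Y_cur = np.full(W, _NEG, np.int64)
    ptr = np.zeros((n + 1, W), np.uint8)
    centers = np.empty(n + 1, np.int64)
    for i in range(n + 1):
        centers[i] = (i * m + n // 2) // n if n > 0 else 0
    # row 0: only horizontal gaps
    c0 = centers[0]
    for off in range(W):
        j = c0 - band + off
        if j < 0 or j > m:
            continue
        if j == 0:
            M_prev[off] = 0
        else:
            prev_off = off - 1
            if prev_off >= 0:
                open_sc = M_prev[prev_off] + gap_open + gap_extend
                ext_sc = Y_prev[prev_off] + gap_extend
                if open_sc >= ext_sc:
                    Y_prev[off] = open_sc
                    ptr[0, off] = 0 << 4
                else:
                    Y_prev[off] = ext_sc
                    ptr[0, off] = 2 << 4
    for i in range(1, n + 1):
        ci = centers[i]
        d = ci - centers[i - 1]
        for off in range(W):
            M_cur[off] = _NEG
            X_cur[off] = _NEG
            Y_cur[off] = _NEG
        for off in range(W):
            j = ci - band + off
            if j < 0 or j > m:
                continue
            p = np.uint8(0)
            # X: gap in b (consume a), from row i-1 same column
            off_up = off + d
            if 0 <= off_up < W:
                best = M_prev[off_up] + gap_open + gap_extend
                src = 0
                if X_prev[off_up] + gap_extend > best:
                    best = X_prev[off_up] + gap_extend
                    src = 1
                if Y_prev[off_up] + gap_open + gap_extend > best:
                    best = Y_prev[off_up] + gap_open + gap_extend
                    src = 2
                if best > _NEG // 2:
                    X_cur[off] = best
                    p |= np.uint8(src << 2)
            # M: diagonal
            if j >= 1:
                off_diag = off + d - 1
                if 0 <= off_diag < W:
                    best = M_prev[off_diag]
                    src = 0
                    if X_prev[off_diag] > best:
                        best = X_prev[off_diag]
                        src = 1
                    if Y_prev[off_diag] > best:
                        best = Y_prev[off_diag]
                        src = 2
                    if best > _NEG // 2:
                        s = match if a[i - 1] == b[j - 1] else mismatch
                        M_cur[off] = best + s
                        p |= np.uint8(src)
            # Y: gap in a (consume b), from same row j-1
            if j >= 1 and off - 1 >= 0:
                best = M_cur[off - 1] + gap_open + gap_extend
                src = 0
                if X_cur[off - 1] + gap_open + gap_extend > best:
                    best = X_cur[off - 1] + gap_open + gap_extend
                    src = 1
                if Y_cur[off - 1] + gap_extend > best:
                    best = Y_cur[off - 1] + gap_extend
                    src = 2
                if best > _NEG // 2:
                    Y_cur[off] = best
                    p |= np.uint8(src << 4)
            ptr[i, off] = p
        M_prev, M_cur = M_cur, M_prev
        X_prev, X_cur = X_cur, X_prev
        Y_prev, Y_cur = Y_cur, Y_prev
    off_end = m - (centers[n] - band)
    if off_end < 0 or off_end >= W:
        return np.empty(0, np.uint8), np.int64(_NEG)
    score = M_prev[off_end]
    state = 0
    if X_prev[off_end] > score:
        score = X_prev[off_end]
        state = 1
    if Y_prev[off_end] > score:
        score = Y_prev[off_end]
        state = 2
    if score <= _NEG // 2:
        return np.empty(0, np.uint8), np.int64(_NEG)
    # traceback
    ops = np.empty(n + m, np.uint8)
    k = 0
    i = n
    j = m
    while i > 0 or j > 0:
        off = j - (centers[i] - band)
        p = ptr[i, off]
        if state == 0:  # M: consume both
            ops[k] = 0
            k += 1
            src = p & 0x3
            i -= 1
            j -= 1
            state = src
        elif state == 1:  # X: consume a
            ops[k] = 1
            k += 1
            src = (p >> 2) & 0x3
            i -= 1
            state = src
        else:  # Y: consume b
            ops[k] = 2
            k += 1
            src = (p >> 4) & 0x3
            j -= 1
            state = src
    return ops[:k][::-1].copy(), score


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def banded_align(
    a: str,
    b: str,
    band: int = DEFAULT_BAND,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -1,
) -> tuple[str, str, int]:
    """Globally align two sequences; returns (aligned_a, aligned_b, score).

    Raises :class:`CollinearityError` when the band is exceeded.
    """
    if not a and not b:
        return "", "", 0
    if not a:
        return "-" * len(b), b, gap_open + gap_extend * len(b)
    if not b:
        return a, "-" * len(a), gap_open + gap_extend * len(a)
    if abs(len(a) - len(b)) > band:
        raise CollinearityError(
            f"length difference {abs(len(a) - len(b))} exceeds band {band}"
        )
    ops, score = _banded_affine_kernel(
        _encode(a), _encode(b), band, match, mismatch, gap_open, gap_extend
    )
    if score <= _NEG // 2:
        raise CollinearityError(
            "optimal path left the alignment band; supply a precomputed alignment"
        )
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for op in ops:
        if op == 0:
            out_a.append(a[ia])
            out_b.append(b[ib])
            ia += 1
            ib += 1
        elif op == 1:
            out_a.append(a[ia])
            out_b.append("-")
            ia += 1
        else:
            out_a.append("-")
            out_b.append(b[ib])
            ib += 1
    assert ia == len(a) and ib == len(b)
    return "".join(out_a), "".join(out_b), int(score)
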