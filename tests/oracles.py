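"""Independent brute-force oracles used by the test suite.

Each oracle implements the same mathematical definition as the package
through a different, simpler algorithm (exhaustive enumeration or full
dynamic programming) so agreement is a meaningful check.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Inverted repeats (structure oracle)


def brute_longest_inverted_pair(seq: str, min_len: int):
    """All maximal disjoint inverted-repeat pairs of maximal length, by
    O(n^2) dynamic programming on the doubled sequence."""
    n = len(seq)
    s2 = seq + seq
    r2 = revcomp(s2)
    a = np.frombuffer(s2.encode(), dtype=np.uint8)
    b = np.frombuffer(r2.encode(), dtype=np.uint8)
    m = len(s2)
    # run[i, j] = length of common substring of s2 starting at i and r2 at j,
    # computed per diagonal
    best: set[tuple[int, int, int]] = set()
    best_len = 0
    for d in range(-(m - min_len), m - min_len + 1):
        lo = max(0, d)
        hi = min(m, m + d)
        if hi - lo < min_len:
            continue
        ai = a[lo:hi]
        bi = b[lo - d : hi - d]
        eq = ai == bi
        # maximal runs of equality
        run = 0
        for k in range(eq.size + 1):
            if k < eq.size and eq[k]:
                run += 1
                continue
            if run >= min_len:
                i0 = lo + k - run
                j0 = i0 - d
                L = min(run, n)
                other = (2 * n - (j0 + L)) % (2 * n)
                p, q = i0 % n, other % n
                if p > q:
                    p, q = q, p
                if p != q:
                    gap = q - p
                    if L <= gap and L <= n - gap:
                        if L > best_len:
                            best_len = L
                            best = {(p, q, L)}
                        elif L == best_len:
                            best.add((p, q, L))
            run = 0
    return best_len, best


# ---------------------------------------------------------------------------
# SSRs


def brute_ssrs(seq: str, thresholds: dict[int, int]):
    """All leftmost-maximal primitive perfect tandem runs, by enumeration."""

    def primitive(motif: str) -> bool:
        m = len(motif)
        return not any(m % d == 0 and motif == motif[:d] * (m // d) for d in range(1, m))

    out = set()
    n = len(seq)
    for m, thr in thresholds.items():
        for i in range(n - m + 1):
            # maximal tract starting at i requires a period break just before
            if i >= 1 and i - 1 + m < n and seq[i - 1] == seq[i - 1 + m]:
                continue
            j = i
            while j + m < n and seq[j] == seq[j + m]:
                j += 1
            if j == i:
                continue
            copies = (j - i + m) // m
            motif = seq[i : i + m]
            if copies >= thr and primitive(motif) and "N" not in seq[i : i + copies * m]:
                out.add((i, i + copies * m, motif, copies))
    return out


# ---------------------------------------------------------------------------
# Global alignment score (full Needleman-Wunsch, affine gaps)


def nw_affine_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-1):
    """Optimal global affine-gap alignment score by full O(nm) DP."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# Pi (all-pairs Hamming per window)


def brute_window_pi(rows: list[str], start: int, end: int, complete_deletion=True):
    """Average over pairs of (differences / compared sites) in a window."""
    k = len(rows)
    missing = [
        [c in "-N" for c in row[start:end]] for row in rows
    ]
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            d = m = 0
            for c in range(end - start):
                if complete_deletion:
                    if any(missing[t][c] for t in range(k)):
                        continue
                elif missing[i][c] or missing[j][c]:
                    continue
                m += 1
                if rows[i][start + c] != rows[j][start + c]:
                    d += 1
            if m:
                vals.append(d / m)
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# In-silico PCR (exhaustive placement scan)


def brute_pcr_min_product(template: str, circular: bool, fwd: str, rev: str,
                          max_mismatch=2, max_product=5000):
    """Smallest product size by scanning every primer placement pair."""
    rc_r = revcomp(rev)
    L = len(template)
    s2 = template + (template[:max_product] if circular else "")

    def sites(probe, exact_idx, limit):
        out = []
        for i in range(min(limit, len(s2) - len(probe) + 1)):
            w = s2[i : i + len(probe)]
            if w[exact_idx] != probe[exact_idx]:
                continue
            mm = sum(1 for x, y in zip(w, probe) if x != y)
            if mm <= max_mismatch:
                out.append(i)
        return out

    fs = sites(fwd, len(fwd) - 1, L)
    rs = sites(rc_r, 0, len(s2))
    sizes = []
    for i in fs:
        for j in rs:
            if j >= i + len(fwd):
                size = j + len(rc_r) - i
                if size <= max_product:
                    sizes.append(size)
    return min(sizes) if sizes else None
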