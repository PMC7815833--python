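"""Free-end-gap (overlap) global alignment and pairwise identity.

Scoring: match +1, mismatch 0, internal gap -1, terminal gaps free.
Identity of a pair is defined deterministically as the lexicographic
optimum over all alignments of (score, matches, -non-terminal columns):
maximise the alignment score, among co-optimal alignments maximise the
match count, then minimise the number of aligned columns excluding
terminal gaps.  Identity = matches / columns (0 when the optimal core is
empty).  The lexicographic objective is additive per alignment column, so
a single-cell dynamic programme is exact and needs no traceback.
"""

from __future__ import annotations

MATCH = 1
MISMATCH = 0
GAP = -1

_NEG = (float("-inf"), 0, 0)


def align_overlap(a: str, b: str) -> tuple[int, int, int]:
    """Best (score, matches, columns) under the lexicographic objective.

    Columns counts aligned positions excluding terminal gaps.  Empty
    sequences give (0, 0, 0).
    """
    m, n = len(a), len(b)
    # dp[j] holds the best (score, matches, -columns) for prefixes a[:i], b[:j]
    # with leading gaps free (row 0 / column 0 pinned to (0, 0, 0)).
    prev = [(0, 0, 0)] * (n + 1)
    best = prev[n]  # i == 0 endpoint (all of a as trailing gap)
    for i in range(1, m + 1):
        cur = [(0, 0, 0)] + [_NEG] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            is_match = 1 if ai == b[j - 1] else 0
            d = prev[j - 1]
            diag = (d[0] + (MATCH if is_match else MISMATCH), d[1] + is_match, d[2] - 1)
            u = prev[j]
            up = (u[0] + GAP, u[1], u[2] - 1)
            l = cur[j - 1]
            left = (l[0] + GAP, l[1], l[2] - 1)
            v = diag
            if up > v:
                v = up
            if left > v:
                v = left
            cur[j] = v
        if cur[n] > best:  # j == n endpoint: rest of a is a free trailing gap
            best = cur[n]
        prev = cur
    for j in range(n + 1):  # i == m endpoints: rest of b free
        if prev[j] > best:
            best = prev[j]
    return best[0], best[1], -best[2]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the optimal overlap alignment,
    excluding terminal gaps; 0.0 when the optimal core is empty."""
    _, matches, columns = align_overlap(a.upper(), b.upper())
    return matches / columns if columns else 0.0
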