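"""Independent reference implementations used to cross-check the package.

These are deliberately written from the textbook definitions (quadratic
Gotoh dynamic programming, explicit window/pair enumeration, backtracking
pattern matching, 2x2 contingency phi) and share no code with the package.
"""

from __future__ import annotations

import math
from collections import Counter

NEG = float("-inf")


def gotoh_global_score(a, b, matrix, gap_open, gap_extend):
    """Affine-gap global alignment score; a gap of length L costs
    gap_open + (L-1)*gap_extend, end gaps penalized."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # a_i over a gap
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # b_j over a gap
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            if j > 0:
                s = matrix[a[i - 1], b[j - 1]]
                M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            if j > 0:
                Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                              X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_local_score(a, b, matrix, gap_open, gap_extend):
    """Affine-gap local alignment score, floored at 0."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
            best = max(best, M[i][j])
    return best


def brute_cooccurrence(sequence):
    """(entropy bits, energy) from explicit 3x3 window/pair enumeration."""
    if len(sequence) < 9:
        return 0.0, 0.0
    pairs = Counter()
    for start in range(len(sequence) - 8):
        window = sequence[start:start + 9]
        rev = window[::-1]
        grid = [list(rev[0:3]), list(rev[3:6]), list(rev[6:9])]
        for row in grid:
            pairs[(row[0], row[1])] += 1
            pairs[(row[1], row[2])] += 1
    total = sum(pairs.values())
    probs = [c / total for c in pairs.values()]
    energy = sum(p * p for p in probs)
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    return entropy, energy


def brute_pattern_matches(elements, sequence):
    """Leftmost non-overlapping matches by explicit backtracking.

    ``elements`` is a list of (kind, residues, min_repeat, max_repeat).
    Greedy-first expansion mirrors regular-expression semantics.
    """

    def single(kind, residues, pos):
        if pos >= len(sequence):
            return False
        ch = sequence[pos]
        if kind == "fixed" or kind == "class":
            return ch in residues
        if kind == "excluded":
            return ch not in residues
        return True  # wildcard

    def match_from(idx, pos):
        if idx == len(elements):
            return pos
        kind, residues, lo, hi = elements[idx]
        for count in range(hi, lo - 1, -1):  # greedy first
            if pos + count > len(sequence):
                continue
            if all(single(kind, residues, pos + k) for k in range(count)):
                end = match_from(idx + 1, pos + count)
                if end is not None:
                    return end
        return None

    out = []
    pos = 0
    while pos <= len(sequence):
        hit = None
        for start in range(pos, len(sequence) + 1):
            end = match_from(0, start)
            if end is not None:
                hit = (start, end)
                break
        if hit is None:
            break
        out.append(hit)
        pos = hit[1] if hit[1] > hit[0] else hit[0] + 1
    return out


def phi_coefficient(x, y):
    """Phi from the 2x2 contingency table of two boolean vectors."""
    n11 = sum(1 for a, b in zip(x, y) if a and b)
    n10 = sum(1 for a, b in zip(x, y) if a and not b)
    n01 = sum(1 for a, b in zip(x, y) if not a and b)
    n00 = sum(1 for a, b in zip(x, y) if not a and not b)
    denom = math.sqrt((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / denom
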