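"""Independent brute-force oracles the test suite checks the package against.

Each oracle is written from the textbook definition, separately from
the implementation it validates.
"""

from __future__ import annotations

import itertools


def sw_oracle(query: str, subject: str, match: float = 1.0, mismatch: float = -1.0,
              gap: float = -2.0):
    """Full-matrix Smith-Waterman with explicit pointer bookkeeping.

    Conventions match the package's documented determinism contract:
    the traceback starts at the first maximal cell in row-major order
    and prefers diagonal > up > left on score ties.  Returns
    (score, identity_percent, coverage_percent) or None when no
    positive-scoring local alignment exists.
    """
    m, n = len(query), len(subject)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = match if query[i - 1] == subject[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, H[i - 1][j] + gap, H[i][j - 1] + gap)
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0.0:
        return None
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0.0:
        sub = match if query[i - 1] == subject[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + sub:
            matches += query[i - 1] == subject[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    identity = 100.0 * matches / columns
    coverage = 100.0 * (bi - i) / m
    return best, identity, coverage


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg step-up: q(i) = min_{k>=i} p(k)*m/k, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, pvalues[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def brute_digest(protein: str, max_missed: int = 2, min_length: int = 4) -> set:
    """All substrings of a protein bounded by tryptic cleavage points.

    A boundary is position 0, len(protein), or any i such that
    protein[i-1] in KR and protein[i] != 'P'.  Internal missed
    cleavages of a candidate are counted directly on the substring.
    """
    boundaries = [0, len(protein)]
    for i in range(1, len(protein)):
        if protein[i - 1] in "KR" and protein[i] != "P":
            boundaries.append(i)
    boundaries = sorted(set(boundaries))
    peptides = set()
    for a, b in itertools.combinations(boundaries, 2):
        pep = protein[a:b]
        if len(pep) < min_length:
            continue
        missed = sum(
            1 for i in range(len(pep) - 1) if pep[i] in "KR" and pep[i + 1] != "P"
        )
        if missed <= max_missed:
            peptides.add(pep)
    return peptides


def ols_line(x, y):
    """Closed-form simple least squares via the normal equations."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def shannon_oracle(proportions):
    """H = -sum p ln p over strictly positive proportions (already normalized)."""
    import math
    return -sum(p * math.log(p) for p in proportions if p > 0)
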