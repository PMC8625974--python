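"""Independent brute-force / textbook reference implementations.

These deliberately avoid scipy and the package's own code paths so that
equivalence tests compare two unrelated routes to the same quantity.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def hypergeom_tail_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def hypergeom_tail_formula(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) via exact rational binomial arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return float(total)


def naive_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def average_ranks(values) -> list[float]:
    """Mean ranks (1-based) with ties sharing the average of their positions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = mean_rank
        i = j + 1
    return ranks


def naive_spearman(x, y) -> float:
    return naive_pearson(average_ranks(list(x)), average_ranks(list(y)))


def bh_stepup_literal(p_values) -> list[float]:
    """Literal Benjamini-Hochberg step-up: q_i = min_{j >= i} p_(j) * m / j."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adjusted_sorted = [0.0] * m
    for rank_pos in range(m):
        candidates = [
            p_values[indexed[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adjusted_sorted[rank_pos] = min(1.0, min(candidates))
    out = [0.0] * m
    for rank_pos, original in enumerate(indexed):
        out[original] = adjusted_sorted[rank_pos]
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_force_seed_scan(mirna_seq: str, target_seq: str):
    """Test every offset against every class pattern, highest class first.

    Returns (start, end, class) tuples; patterns built independently from
    first principles (complement of seed, reversed, plus target A).
    """
    m = mirna_seq.upper().replace("U", "T")
    t = target_seq.upper().replace("U", "T")
    seed28 = m[1:8]
    seed27 = m[1:7]
    patterns = [
        ("8mer", _rc(seed28) + "A"),
        ("7mer-m8", _rc(seed28)),
        ("7mer-A1", _rc(seed27) + "A"),
        ("6mer", _rc(seed27)),
    ]
    found = []
    for start in range(len(t)):
        for cls, pat in patterns:
            if t[start : start + len(pat)] == pat and len(pat) <= len(t) - start:
                found.append((start, start + len(pat), cls))
                break
    return found
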