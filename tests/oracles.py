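"""Brute-force oracles used by the test suite.

Each oracle computes the same quantity as a production routine by direct
enumeration, with no shared code paths beyond elementary primitives, so a
disagreement always implicates the production implementation (or the
oracle's reading of the definition), never a shared bug.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

NEG_INF = float("-inf")


def oracle_align_score(
    a: str, b: str, matrix: np.ndarray, index: dict[str, int], gap_open: int, gap_extend: int
) -> float:
    """Optimal global affine-gap alignment score by exhaustive recursion.

    A gap run of length L costs gap_open + L * gap_extend, charged once per
    run. Feasible for short sequences only (the recursion is memoized over
    (i, j, state) so it is O(len(a) * len(b)) states, but kept simple and
    obviously correct rather than fast).
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = NEG_INF
        if i < len(a) and j < len(b):
            s = matrix[index[a[i]], index[b[j]]]
            out = max(out, s + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "A" else gap_open + gap_extend
            out = max(out, -cost + best(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if state == "B" else gap_open + gap_extend
            out = max(out, -cost + best(i, j + 1, "B"))
        return out

    return best(0, 0, "M")


def oracle_hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by enumerating every size-n subset of a size-N universe.

    The first K universe elements are the "successes"; the tail counts
    subsets holding at least k of them. Exact rational arithmetic via
    integer counts divided once at the end.
    """
    universe = range(N)
    successes = set(range(K))
    hits = 0
    total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(successes.intersection(subset)) >= k:
            hits += 1
    return hits / total


def oracle_hypergeom_upper_tail_comb(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) from the hypergeometric pmf written with binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    ) / total


def oracle_bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values from the textbook step-up formula."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m - 1, -1, -1):
        i = order[rank_from_end]
        rank = rank_from_end + 1
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def oracle_greedy_clusters(
    sequences: list[tuple[str, str]], identity, threshold: float
) -> list[list[str]]:
    """Greedy longest-first clustering with an injected identity function.

    Independent control flow mirroring the documented rule: visit isoforms
    by descending length (ties by ascending id); join the first cluster
    whose FOUNDER reaches the threshold, else found a new cluster.
    """
    order = sorted(sequences, key=lambda t: (-len(t[1]), t[0]))
    founders: list[str] = []
    members: list[list[str]] = []
    for sid, seq in order:
        for ci, founder_seq in enumerate(founders):
            if identity(seq, founder_seq) >= threshold:
                members[ci].append(sid)
                break
        else:
            founders.append(seq)
            members.append([sid])
    return members


def oracle_interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the closed-interval intersection, by point enumeration."""
    return len(set(range(a[0], a[1] + 1)) & set(range(b[0], b[1] + 1)))
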