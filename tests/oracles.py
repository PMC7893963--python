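"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately naive: full-matrix dynamic programming in
plain Python, brute-force k-mer table joins, pairwise union-find, and exact
integer hypergeometric enumeration.  None of it shares code with the
package modules it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache


def sw_oracle(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = 2, boundary=None):
    """Full-matrix linear-gap local alignment of query ``b`` against ``a``.

    Returns (score, bc_errors, umi_errors) under the package's documented
    conventions: the optimum cell is the first best in row-major order;
    traceback prefers diagonal, then gap-in-query, then gap-in-target;
    errors = mismatches + gap bases in the optimal path + unaligned query
    bases, attributed to the query segment before/after ``boundary``.
    """
    la, lb = len(a), len(b)
    if boundary is None:
        boundary = lb
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            v = max(0, H[i - 1][j - 1] + s, H[i - 1][j] - gap, H[i][j - 1] - gap)
            H[i][j] = v
            if v > best:
                best, bi, bj = v, i, j
    bc = umi = 0

    def hit(pos):
        nonlocal bc, umi
        if pos < boundary:
            bc += 1
        else:
            umi += 1

    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            if s == mismatch:
                hit(j - 1)
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] - gap:
            hit(j - 1)
            i -= 1
        else:
            hit(j - 1)
            j -= 1
    for p in range(j):
        hit(p)
    for p in range(bj, lb):
        hit(p)
    return best, bc, umi


def seed_oracle(flank: str, query: str, word_size: int = 7) -> list[int]:
    """Brute-force k-mer table join over all (flank, query) position pairs."""
    hits = set()
    for i in range(len(flank) - word_size + 1):
        for j in range(len(query) - word_size + 1):
            if flank[i : i + word_size] == query[j : j + word_size]:
                hits.add(i)
    return sorted(hits)


def polya_union_find(sites, threshold: int = 24) -> list[tuple[int, ...]]:
    """Pairwise union-find clustering: link every pair within the threshold."""
    sites = list(sites)
    parent = list(range(len(sites)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if abs(sites[i] - sites[j]) <= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(sites):
        groups.setdefault(find(i), []).append(s)
    return sorted(tuple(sorted(g)) for g in groups.values())


@lru_cache(maxsize=None)
def _hypergeom_numerators(r1: int, r2: int, c1: int) -> tuple[tuple[int, ...], int]:
    """Integer pmf numerators over the support of a 2x2 table's margins."""
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    nums = tuple(math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1))
    return nums, lo


def fisher_enumeration(table) -> float:
    """Exact two-sided Fisher p by integer hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    exact (rational) probability does not exceed the observed table's.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    nums, lo = _hypergeom_numerators(r1, r2, c1)
    obs = nums[a - lo]
    total = sum(nums)
    return sum(n for n in nums if n <= obs) / total
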