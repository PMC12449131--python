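"""Independent top-down recursive-with-memoization oracle.

Evaluates the local-alignment recursions directly from their definitions,
on plain Python ints and strings, sharing no code with the package's
kernels.  Deliberately slow and simple; used only on small inputs.
"""

import sys
from functools import lru_cache

ORACLE_NEG = -(10**9)


def oracle_matrices(p: str, q: str, match: int, mismatch: int, goe: int, ge: int):
    """Full H, E, F tables as lists of lists (shape (m+1) x (n+1))."""
    m, n = len(p), len(q)
    sys.setrecursionlimit(max(10000, 50 * (m + n)))

    @lru_cache(maxsize=None)
    def E(i, j):
        if j == 0:
            return ORACLE_NEG
        return max(H(i, j - 1) - goe, E(i, j - 1) - ge)

    @lru_cache(maxsize=None)
    def F(i, j):
        if i == 0:
            return ORACLE_NEG
        return max(H(i - 1, j) - goe, F(i - 1, j) - ge)

    @lru_cache(maxsize=None)
    def H(i, j):
        if i == 0 or j == 0:
            return 0
        a, b = p[i - 1], q[j - 1]
        s = match if (a == b and a != "N") else mismatch
        return max(0, H(i - 1, j - 1) + s, E(i, j), F(i, j))

    Ht = [[H(i, j) for j in range(n + 1)] for i in range(m + 1)]
    Et = [[E(i, j) for j in range(n + 1)] for i in range(m + 1)]
    Ft = [[F(i, j) for j in range(n + 1)] for i in range(m + 1)]
    return Ht, Et, Ft


def oracle_best(p: str, q: str, match: int, mismatch: int, goe: int, ge: int):
    """(score, i, j) of the H maximum, ties by smallest i then j."""
    Ht, _, _ = oracle_matrices(p, q, match, mismatch, goe, ge)
    best, bi, bj = 0, None, None
    for i, row in enumerate(Ht):
        for j, v in enumerate(row):
            if v > best:
                best, bi, bj = v, i, j
    return best, bi, bj
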