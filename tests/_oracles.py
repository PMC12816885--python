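"""Independent reference implementations used only as test oracles.

These deliberately use different algorithms/code paths from the package:
a pure-Python exhaustive Gotoh DP with full co-optimal traceback
enumeration, a naive recursive RED computation that re-walks the tree
for every node, and a brute-force global-alignment enumerator for tiny
nucleotide sequences.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_affine_oracle(a: str, b: str, gap_open: float = 11.0,
                     gap_extend: float = 1.0, max_tracebacks: int = 2000):
    """Exhaustive local affine-gap DP (Gotoh).

    Gap convention matches a first-gap-position cost of ``gap_open`` and
    ``gap_extend`` for each further position.  Returns
    ``(best_score, co_optimal)`` where ``co_optimal`` is a set of
    ``(identities, columns)`` tuples over all optimal local alignments
    (capped at *max_tracebacks* paths).  ``best_score`` is 0.0 with an
    empty set when no positive-scoring alignment exists.
    """
    m, n = len(a), len(b)
    s = [[float(_BLOSUM62[ca][cb]) for cb in b] for ca in a]
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consumes b)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = s[i - 1][j - 1] + diag
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    if best <= 0.0:
        return 0.0, set()

    results: set[tuple[int, int]] = set()
    budget = [max_tracebacks]

    def walk(state: str, i: int, j: int, idents: int, cols: int) -> None:
        if budget[0] <= 0:
            return
        if state == "M":
            here = M[i][j]
            idents2 = idents + (1 if a[i - 1] == b[j - 1] else 0)
            cols2 = cols + 1
            prev = here - s[i - 1][j - 1]
            if abs(prev - 0.0) < 1e-9:  # local start
                budget[0] -= 1
                results.add((idents2, cols2))
                # other co-optimal starts may continue below; fall through
            for st, val in (("M", M[i - 1][j - 1]), ("Ix", Ix[i - 1][j - 1]),
                            ("Iy", Iy[i - 1][j - 1])):
                if val > 0 and abs(val - prev) < 1e-9:
                    walk(st, i - 1, j - 1, idents2, cols2)
        elif state == "Ix":
            here = Ix[i][j]
            if abs(M[i - 1][j] - gap_open - here) < 1e-9:
                walk("M", i - 1, j, idents, cols + 1)
            if abs(Ix[i - 1][j] - gap_extend - here) < 1e-9:
                walk("Ix", i - 1, j, idents, cols + 1)
        else:
            here = Iy[i][j]
            if abs(M[i][j - 1] - gap_open - here) < 1e-9:
                walk("M", i, j - 1, idents, cols + 1)
            if abs(Iy[i][j - 1] - gap_extend - here) < 1e-9:
                walk("Iy", i, j - 1, idents, cols + 1)

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if abs(M[i][j] - best) < 1e-9:
                walk("M", i, j, 0, 0)
    return best, results


def red_recursive_oracle(tree):
    """RED per node by naive recursion, re-walking leaf distances each call.

    Returns {id(node): red} matching the package keying.
    """
    def mean_leaf_dist(node) -> float:
        leaves = [lf for lf in node.leaf_iter()]
        total = 0.0
        for lf in leaves:
            d = 0.0
            cur = lf
            while cur is not node:
                d += cur.edge.length or 0.0
                cur = cur.parent_node
            total += d
        return total / len(leaves)

    red: dict[int, float] = {}

    def visit(node, parent_red: float) -> None:
        if node.parent_node is None:
            red[id(node)] = 0.0
            my = 0.0
        elif node.is_leaf():
            red[id(node)] = 1.0
            return
        else:
            d = node.edge.length or 0.0
            u = d + mean_leaf_dist(node)
            my = parent_red + (1.0 - parent_red) * d / u
            red[id(node)] = my
        for ch in node.child_nodes():
            visit(ch, my)

    visit(tree.seed_node, 0.0)
    return red


def enumerate_global_identity(a: str, b: str, match: float = 1.0,
                              mismatch: float = -1.0, gap: float = -2.0):
    """Best global alignment score and the identities achievable at that
    score, by exhaustive recursion (tiny sequences only)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        # returns dict (identities, columns) -> best score? We need best
        # score overall and identity set at best score; enumerate states.
        if i == len(a) and j == len(b):
            return {(0, 0): 0.0}
        out: dict[tuple[int, int], float] = {}

        def add(key, val):
            if key not in out or val > out[key]:
                out[key] = val

        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            for (idn, cols), sc in rec(i + 1, j + 1).items():
                add((idn + (1 if a[i] == b[j] else 0), cols + 1), sc + sub)
        if i < len(a):
            for (idn, cols), sc in rec(i + 1, j).items():
                add((idn, cols + 1), sc + gap)
        if j < len(b):
            for (idn, cols), sc in rec(i, j + 1).items():
                add((idn, cols + 1), sc + gap)
        return out

    table = rec(0, 0)
    best = max(table.values())
    idents = {100.0 * idn / cols for (idn, cols), sc in table.items()
              if abs(sc - best) < 1e-9}
    return best, idents
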