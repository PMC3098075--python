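"""Independent reference implementations used only to cross-check the package.

These deliberately mirror the defining recursions/formulas as literally as
possible (memoized recursion for the alignments, explicit double loops for
SimRank) and share no code with the implementation under test.
"""

from __future__ import annotations

from functools import lru_cache

from tcmnorm.literal_metrics import AlignmentScoring

NEG = float("-inf")


def smith_waterman_recursive(s: str, s2: str, sc: AlignmentScoring) -> float:
    """Linear-gap local alignment straight from the cell recursion."""

    @lru_cache(maxsize=None)
    def H(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return 0.0
        sub = sc.match if s[i - 1] == s2[j - 1] else sc.mismatch
        return max(0.0, H(i - 1, j - 1) + sub, H(i - 1, j) + sc.gap, H(i, j - 1) + sc.gap)

    best = max(H(i, j) for i in range(len(s) + 1) for j in range(len(s2) + 1))
    return min(best / (sc.match * min(len(s), len(s2))), 1.0)


def smith_waterman_gotoh_recursive(s: str, s2: str, sc: AlignmentScoring) -> float:
    """Affine-gap local alignment from the three-state recursion."""

    @lru_cache(maxsize=None)
    def H(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return 0.0
        sub = sc.match if s[i - 1] == s2[j - 1] else sc.mismatch
        return max(0.0, H(i - 1, j - 1) + sub, E(i, j), F(i, j))

    @lru_cache(maxsize=None)
    def E(i: int, j: int) -> float:  # gap consuming s2
        if j == 0:
            return NEG
        return max(H(i, j - 1) + sc.gap_open, E(i, j - 1) + sc.gap_extend)

    @lru_cache(maxsize=None)
    def F(i: int, j: int) -> float:  # gap consuming s
        if i == 0:
            return NEG
        return max(H(i - 1, j) + sc.gap_open, F(i - 1, j) + sc.gap_extend)

    best = max(H(i, j) for i in range(len(s) + 1) for j in range(len(s2) + 1))
    return min(best / (sc.match * min(len(s), len(s2))), 1.0)


def jaro_formula(s: str, s2: str) -> float:
    """Jaro from its printed formula with independently computed m and t."""
    window = max(max(len(s), len(s2)) // 2 - 1, 0)
    used = set()
    pairs = []
    for i, ch in enumerate(s):
        for j in range(max(0, i - window), min(len(s2), i + window + 1)):
            if j not in used and s2[j] == ch:
                used.add(j)
                pairs.append((i, j))
                break
    m = len(pairs)
    if m == 0:
        return 0.0
    order_s = [ch for i, _ in sorted(pairs) for ch in s[i]]
    order_s2 = [ch for _, j in sorted(pairs, key=lambda p: p[1]) for ch in s2[j]]
    t = sum(a != b for a, b in zip(order_s, order_s2)) / 2
    return (m / len(s) + m / len(s2) + (m - t) / m) / 3


def simrank_double_loop(
    neighbors_s: list[set[int]], n_remedies: int, C: float, k_max: int
) -> tuple[list[list[float]], list[list[float]]]:
    """Truncated bipartite SimRank as a literal double-loop transcription.

    ``neighbors_s[i]`` is the remedy-index set of symptom i; remedy
    neighborhoods are derived from it.  Both tables start as identities,
    each iteration reads only the previous iteration's tables, diagonals
    stay 1 and empty neighborhoods give 0.
    """
    n_s = len(neighbors_s)
    neighbors_r = [set() for _ in range(n_remedies)]
    for i, remedies in enumerate(neighbors_s):
        for r in remedies:
            neighbors_r[r].add(i)

    sim_s = [[1.0 if a == b else 0.0 for b in range(n_s)] for a in range(n_s)]
    sim_r = [[1.0 if a == b else 0.0 for b in range(n_remedies)] for a in range(n_remedies)]
    for _ in range(k_max):
        new_s = [[0.0] * n_s for _ in range(n_s)]
        for a in range(n_s):
            for b in range(n_s):
                if a == b:
                    new_s[a][b] = 1.0
                    continue
                R, R2 = neighbors_s[a], neighbors_s[b]
                if not R or not R2:
                    continue
                total = 0.0
                for ri in R:
                    for rj in R2:
                        total += sim_r[ri][rj]
                new_s[a][b] = C / (len(R) * len(R2)) * total
        new_r = [[0.0] * n_remedies for _ in range(n_remedies)]
        for a in range(n_remedies):
            for b in range(n_remedies):
                if a == b:
                    new_r[a][b] = 1.0
                    continue
                S, S2 = neighbors_r[a], neighbors_r[b]
                if not S or not S2:
                    continue
                total = 0.0
                for si in S:
                    for sj in S2:
                        total += sim_s[si][sj]
                new_r[a][b] = C / (len(S) * len(S2)) * total
        sim_s, sim_r = new_s, new_r
    return sim_s, sim_r
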