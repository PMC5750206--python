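"""Independent brute-force oracles used only by the tests.

Each oracle is deliberately coded from first principles, separate from the
package's implementation path, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from itertools import combinations


def edit_distance_dp(a: str, b: str) -> int:
    """Plain O(nm) unit-cost Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def best_chain_exhaustive(anchors: list[tuple[int, int]], max_gap: int) -> int:
    """Longest strictly-monotone chain over (rank_a, rank_b) anchors, either
    orientation, with rank gaps <= max_gap on both sides; depth-first search."""
    n = len(anchors)
    best = 0

    def ok(prev, cur, sign):
        ra0, rb0 = prev
        ra1, rb1 = cur
        if ra1 <= ra0 or ra1 - ra0 - 1 > max_gap:
            return False
        db = sign * (rb1 - rb0)
        return db > 0 and db - 1 <= max_gap

    def dfs(last_idx, length, sign):
        nonlocal best
        best = max(best, length)
        for i in range(n):
            if last_idx is None or (i != last_idx and ok(anchors[last_idx], anchors[i], sign)):
                if last_idx is None or anchors[i][0] > anchors[last_idx][0]:
                    dfs(i, length + 1, sign)

    for sign in (1, -1):
        dfs(None, 0, sign)
    return best


def midranks(values: list[float]) -> list[float]:
    """Mid-ranks, written independently of scipy.rankdata."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for idx in order[i:j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def rank_sum_p_exhaustive(x: list[float], y: list[float],
                          alternative: str = "two-sided") -> tuple[float, float]:
    """Exact rank-sum p by full enumeration of group assignments.

    Returns (W of x, p-value). Valid with ties via mid-ranks.
    """
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    nx, N = len(x), len(pooled)
    w_obs = sum(ranks[:nx])
    mu = nx * (N + 1) / 2.0
    eps = 1e-9
    n_extreme = total = 0
    for idx in combinations(range(N), nx):
        w = sum(ranks[i] for i in idx)
        total += 1
        if alternative == "two-sided":
            n_extreme += abs(w - mu) >= abs(w_obs - mu) - eps
        elif alternative == "greater":
            n_extreme += w >= w_obs - eps
        else:
            n_extreme += w <= w_obs + eps
    return w_obs, n_extreme / total
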