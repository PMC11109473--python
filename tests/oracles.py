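"""Independent reference implementations used only to check the package.

Everything here is written from first principles (naive loops, explicit
enumeration, textbook formulas) and deliberately shares no code with the
implementation under test.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_force_permutation_p(
    a: np.ndarray, b: np.ndarray, statistic: str = "mean_diff"
) -> float:
    """Exhaustive two-sided permutation p by looping over all labelings."""
    pooled = list(a) + list(b)
    na = len(a)

    def stat(group_a, group_b):
        if statistic == "rank_sum":
            order = sorted(range(len(pooled)), key=lambda i: pooled[i])
            # midranks computed naively
            ranks = [0.0] * len(pooled)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
                    j += 1
                r = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = r
                i = j + 1
            return sum(ranks[i] for i in group_a) - na * (len(pooled) + 1) / 2
        ma = sum(pooled[i] for i in group_a) / len(group_a)
        mb = sum(pooled[i] for i in group_b) / len(group_b)
        d = ma - mb
        return abs(d) if statistic == "abs_mean_diff" else d

    all_idx = set(range(len(pooled)))
    t_obs = stat(list(range(na)), list(range(na, len(pooled))))
    thresh = abs(t_obs) - 1e-12 * max(1.0, abs(t_obs))
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        rest = sorted(all_idx - set(combo))
        if abs(stat(list(combo), rest)) >= thresh:
            count += 1
        total += 1
    return count / total


def stepup_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up written directly from its definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def rank_sum_tail_p(a: list[float], b: list[float]) -> float:
    """Two-sided rank-sum p by enumerating every labeling's rank sum."""
    pooled = sorted(a + b)
    ranks = {}
    for i, v in enumerate(pooled):
        ranks.setdefault(v, []).append(i + 1)
    def r(v):
        return sum(ranks[v]) / len(ranks[v])
    na = len(a)
    obs = sum(r(v) for v in a)
    center = na * (len(pooled) + 1) / 2
    vals = []
    allv = a + b
    for combo in itertools.combinations(range(len(allv)), na):
        vals.append(sum(r(allv[i]) for i in combo))
    vals = np.array(vals)
    return float(np.mean(np.abs(vals - center) >= abs(obs - center) - 1e-12))


def kruskal_h(groups: list[list[float]]) -> float:
    """Tie-free Kruskal–Wallis H from the textbook rank formula."""
    pooled = sorted(v for g in groups for v in g)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    h = 0.0
    for g in groups:
        rsum = sum(rank[v] for v in g)
        h += rsum**2 / len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def spearman_rho_distinct(x: list[float], y: list[float]) -> float:
    """ρ = 1 − 6Σd²/(n(n²−1)) for profiles with distinct values."""
    n = len(x)
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1 - 6 * d2 / (n * (n**2 - 1))


def subset_sum_counts(n_total: int, n_pick: int) -> dict[int, int]:
    """Counts of rank-sum values over all size-``n_pick`` subsets of 1..n_total.

    Dynamic programming over items; used to build exact null distributions
    of rank statistics without enumerating subsets.
    """
    # table[k][s] = number of k-subsets with sum s
    max_sum = sum(range(n_total - n_pick + 1, n_total + 1))
    table = [dict() for _ in range(n_pick + 1)]
    table[0][0] = 1
    for item in range(1, n_total + 1):
        for k in range(min(n_pick, item) - 1, -1, -1):
            for s, c in list(table[k].items()):
                if s + item <= max_sum:
                    table[k + 1][s + item] = table[k + 1].get(s + item, 0) + c
    assert sum(table[n_pick].values()) == comb(n_total, n_pick)
    return table[n_pick]


def signed_rank_counts(n: int) -> dict[float, int]:
    """Counts of W+ over all 2^n sign assignments to ranks 1..n."""
    counts = {0.0: 1}
    for r in range(1, n + 1):
        new: dict[float, int] = {}
        for s, c in counts.items():
            for add in (0.0, float(r)):
                new[s + add] = new.get(s + add, 0) + c
        counts = new
    return counts
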