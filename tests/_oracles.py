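"""Independent brute-force oracles used by the test suite.

These are deliberately separate implementations (direct textbook formulas
and full enumeration) kept free of any pupfast internals, so they can
vouch for the package's statistics rather than echo them.
"""

import itertools

import numpy as np
from scipy import stats


def oracle_kw_h(groups):
    """Textbook Kruskal–Wallis H with tie correction, computed directly."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-ranks, 1-based
        i = j
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx : idx + len(g)]
        h += r.sum() ** 2 / len(g)
        idx += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    c = 1 - np.sum(t**3 - t) / (n**3 - n)
    return h / c if c > 0 else 0.0


def oracle_exact_p(groups):
    """Exact permutation tail probability by full enumeration."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = oracle_kw_h(groups)
    count = total = 0
    for perm in set(itertools.permutations(range(len(pooled)))):
        vals = pooled[list(perm)]
        out, idx = [], 0
        for s in sizes:
            out.append(vals[idx : idx + s])
            idx += s
        total += 1
        if oracle_kw_h(out) >= h_obs - 1e-12:
            count += 1
    return count / total


def oracle_dunn_z(groups):
    """Textbook Dunn z statistics for all pairs, with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    idx, mean_ranks = 0, []
    for g in groups:
        mean_ranks.append(ranks[idx : idx + len(g)].mean())
        idx += len(g)
    _, t = np.unique(pooled, return_counts=True)
    ties = np.sum(t**3 - t)
    zs = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        sigma = np.sqrt(
            (n * (n + 1) / 12.0 - ties / (12.0 * (n - 1)))
            * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        )
        zs.append((mean_ranks[i] - mean_ranks[j]) / sigma)
    return np.array(zs)
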