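"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: segmentation cost
by exhaustive enumeration of all breakpoint subsets, and BH adjustment
straight from the definition in O(m^2).
"""

import numpy as np


def brute_force_pcf_cost(y, gamma, min_size=1):
    """Minimum of sum-of-SSE + gamma*(k-1) over all 2^(n-1) segmentations."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    # SSE of every [i, j] inclusive
    sse = [[0.0] * n for _ in range(n)]
    for i in range(n):
        s = s2 = 0.0
        for j in range(i, n):
            s += y[j]
            s2 += y[j] * y[j]
            length = j - i + 1
            sse[i][j] = s2 - s * s / length
    best = np.inf
    for mask in range(1 << (n - 1)):
        cost = 0.0
        start = 0
        feasible = True
        nseg = 0
        for pos in range(n - 1):
            if mask >> pos & 1:
                if pos + 1 - start < min_size:
                    feasible = False
                    break
                cost += sse[start][pos]
                nseg += 1
                start = pos + 1
        if not feasible or n - start < min_size:
            continue
        cost += sse[start][n - 1] + gamma * nseg
        if cost < best:
            best = cost
    return best


def naive_bh(p):
    """BH from the definition: q_(i) = min_{j>=i} m*p_(j)/j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[rank_j - 1]] / rank_j for rank_j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q
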