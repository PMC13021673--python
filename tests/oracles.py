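"""Independent reference implementations used only to cross-check results.

Deliberately naive (explicit loops, direct formulas) and kept separate
from the library code paths they verify.
"""

import math

import numpy as np
from scipy.cluster.hierarchy import linkage


def naive_network_metrics(entries, member_rows):
    """Triple-loop L, N, A, D over the rows listed in member_rows."""
    load = 0
    signed = 0
    abnormal_rows = set()
    for r in member_rows:
        for s in range(entries.shape[1]):
            v = int(entries[r, s])
            if v != 0:
                load += 1
                signed += v
                abnormal_rows.add(r)
    n_distinct = len(abnormal_rows)
    a = load / n_distinct if n_distinct else math.nan
    d = signed / load if load else math.nan
    return load, n_distinct, a, d


def naive_coalteration(entries):
    """Triple-loop pair-count matrix C (including the diagonal)."""
    n = entries.shape[0]
    c = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            for s in range(entries.shape[1]):
                if entries[i, s] != 0 and entries[j, s] != 0:
                    c[i, j] += 1
    return c


def scipy_ward_heights(points):
    """Sorted Ward merge heights from the scipy reference implementation."""
    return np.sort(linkage(np.asarray(points, dtype=float), method="ward")[:, 2])


def contingency_ari(labels_a, labels_b):
    """Adjusted Rand index evaluated directly from the contingency table."""
    a_vals = sorted(set(labels_a))
    b_vals = sorted(set(labels_b))
    table = np.zeros((len(a_vals), len(b_vals)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        table[a_vals.index(x), b_vals.index(y)] += 1

    def comb2(x):
        return x * (x - 1) // 2

    n = table.sum()
    sum_ij = sum(comb2(v) for v in table.ravel())
    sum_a = sum(comb2(v) for v in table.sum(axis=1))
    sum_b = sum(comb2(v) for v in table.sum(axis=0))
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
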