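"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the blink oracle is a
plain frame-by-frame scan, and the Mann-Whitney oracle enumerates every
label assignment.
"""

from itertools import combinations

import numpy as np


def brute_force_blinks(ear, threshold=0.2):
    """Frame-by-frame scan for sub-threshold runs; returns
    (start, end, complete) triples."""
    ear = list(ear)
    n = len(ear)

    def is_closed(k):
        return not np.isnan(ear[k]) and ear[k] < threshold

    def is_open(k):
        return 0 <= k < n and not np.isnan(ear[k]) and ear[k] > threshold

    events = []
    k = 0
    while k < n:
        if not is_closed(k):
            k += 1
            continue
        start = k
        while k + 1 < n and is_closed(k + 1):
            k += 1
        events.append((start, k, is_open(start - 1) and is_open(k + 1)))
        k += 1
    return events


def mann_whitney_u_exact(group1, group2):
    """Exact two-sided Mann-Whitney p by full enumeration (handles ties)."""
    pooled = list(group1) + list(group2)
    n1 = len(group1)
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    mu = n1 * (n - n1) / 2.0

    def u_of(indices):
        r1 = sum(ranks[i] for i in indices)
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    dev = abs(u_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total
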