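"""Independent reference implementations ("oracles") shared by the test-suite.

Every function here recomputes a quantity from first principles, by a route
deliberately different from the package implementation it checks.
"""

import math
from functools import lru_cache

import numpy as np


def entropy_oracle_mi(x, y):
    """H(X) + H(Y) - H(X,Y) computed from scratch, in bits."""

    def h(labels):
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        return -np.sum(p * np.log2(p))

    joint = [f"{a}|{b}" for a, b in zip(x, y)]
    return h(x) + h(y) - h(joint)


def oracle_cmi(a_bin, b_raw, risk, fraction=0.35, rng=None):
    """From-first-principles CMI: explicit sort, tail strata, entropy MI."""
    n = len(b_raw)
    idx = np.arange(n)
    if rng is not None:
        idx = rng.permutation(n)
    order = idx[np.argsort(np.asarray(b_raw)[idx], kind="stable")]
    k = math.floor(fraction * n)
    low, high = order[:k], order[-k:]
    a = np.asarray(a_bin)
    r = np.asarray(risk)
    return entropy_oracle_mi(a[high], r[high]) - entropy_oracle_mi(a[low], r[low])


def brute_force_matching_size(n_nodes: int, edges) -> int:
    """Exhaustive maximum matching via bitmask recursion over out-copies."""
    adj = [0] * n_nodes
    for u, v in edges:
        adj[u] |= 1 << v

    @lru_cache(maxsize=None)
    def best(i: int, used: int) -> int:
        if i == n_nodes:
            return 0
        top = best(i + 1, used)
        free = adj[i] & ~used
        while free:
            bit = free & -free
            free ^= bit
            top = max(top, 1 + best(i + 1, used | bit))
        return top

    res = best(0, 0)
    best.cache_clear()
    return res


def logrank_oracle(times, events, groups):
    """Hand-computed two-group log-rank chi-square via per-time 2x2 tables."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def concordance_auc(scores, labels):
    """Brute-force Mann--Whitney AUC over all label-discordant pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
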