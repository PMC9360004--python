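"""Independent reference implementations used only as test oracles.

Everything here is deliberately naive and coded straight from the rule
statements, separately from the production code paths it checks.
"""

from itertools import combinations
from math import comb

import numpy as np

TREND_LABELS_ABUNDANCE = {
    ("up", "up"): "G1",
    ("up", "down"): "G2",
    ("none", "up"): "G3",
    ("down", "down"): "G4",
    ("down", "up"): "G5",
    ("none", "down"): "G6",
}
TREND_LABELS_OCCUPANCY = {
    ("up", "up"): "G7",
    ("up", "down"): "G8",
    ("none", "up"): "G9",
    ("none", "down"): "G10",
    ("down", "up"): "G11",
    ("down", "down"): "G12",
}


def naive_temporal(acute, chronic, overall, cutoff, channel):
    """Direct transliteration of the grouping prose, rule by rule."""

    def sign(v):
        if v >= cutoff:
            return "up"
        if v <= -cutoff:
            return "down"
        return "none"

    sa, sc = sign(acute), sign(chronic)
    table = TREND_LABELS_ABUNDANCE if channel == "abundance" else TREND_LABELS_OCCUPANCY
    if sa == "none":
        # the none/up and none/down rules additionally constrain the overall contrast
        if sc == "up" and overall >= cutoff:
            return table[("none", "up")]
        if sc == "down" and overall <= -cutoff:
            return table[("none", "down")]
        return "none"
    if sc == "none":
        return "none"
    return table[(sa, sc)]


def naive_mode(x, y, cutoff):
    """Direct transliteration of the four regulation-mode inequalities."""
    if -cutoff <= (x - y) < cutoff and x >= cutoff and y >= cutoff:
        return "up_both"
    if (x - y) < -cutoff and y > cutoff:
        return "up_occ_only"
    if -cutoff <= (x - y) < cutoff and x <= -cutoff and y <= -cutoff:
        return "down_both"
    if (x - y) > cutoff and y < -cutoff:
        return "down_occ_only"
    return "none"


def hypergeom_tail_enumeration(N, K, n, k):
    """P(X >= k) by exhaustively enumerating all n-subsets of an N-universe."""
    universe = list(range(N))
    special = set(range(K))
    hits = 0
    total = comb(N, n)
    for subset in combinations(universe, n):
        if len(special.intersection(subset)) >= k:
            hits += 1
    return hits / total


def bh_stepup(pvals, alpha):
    """Classic Benjamini-Hochberg step-up: returns the boolean reject vector."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    reject = np.zeros(m, dtype=bool)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= alpha * rank / m:
            k_max = rank
    reject[order[:k_max]] = True
    return reject


def rpkm_cell(count, length_nt, total_reads):
    """Single-cell RPKM formula, evaluated one value at a time."""
    return count / (length_nt / 1000.0) / (total_reads / 1e6)


def permutation_pvalue(a, b, n_perm, rng):
    """Two-sided permutation p-value on the difference of group means."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[: len(a)].mean() - perm[len(a):].mean()) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
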