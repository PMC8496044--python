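"""Independent brute-force oracles used only by the tests.

Deliberately written as plain loops, separate from the package's vectorized
implementations, so agreement between the two is informative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_running_sum(scores, is_hit, weight=1.0):
    """Direct recomputation of the weighted KS running sum, position by position."""
    scores = list(scores)
    is_hit = list(is_hit)
    n = len(scores)
    n_hits = sum(is_hit)
    assert 0 < n_hits < n
    denom = sum(abs(s) ** weight for s, h in zip(scores, is_hit) if h)
    running = []
    acc = 0.0
    for s, h in zip(scores, is_hit):
        if h:
            acc += (abs(s) ** weight) / denom if denom > 0 else 1.0 / n_hits
        else:
            acc -= 1.0 / (n - n_hits)
        running.append(acc)
    peak = max(range(n), key=lambda i: (abs(running[i]), -i))
    return running[peak], running, peak


def rank_average_ties(values):
    """Average ranks, 1-based."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y):
    """Rank both vectors with average ties, then Pearson on the ranks."""
    rx, ry = rank_average_ties(x), rank_average_ties(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


def spearman_exact_perm_p(x, y):
    """Two-sided permutation p over all n! orderings of y."""
    obs = abs(spearman_brute(x, y))
    n = len(y)
    hits = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_brute(x, perm)) >= obs - 1e-12:
            hits += 1
    return hits / total


def hypergeom_table_prob(a, b, c, d):
    """P(this 2x2 table | fixed margins) under the hypergeometric law."""
    return (
        math.comb(a + b, a) * math.comb(c + d, c) / math.comb(a + b + c + d, a + c)
    )


def fisher_two_tailed_brute(a, b, c, d):
    """Sum the probability of every table (same margins) no more likely than
    the observed one."""
    row1, row2, col1 = a + b, c + d, a + c
    p_obs = hypergeom_table_prob(a, b, c, d)
    total = 0.0
    for aa in range(max(0, col1 - row2), min(row1, col1) + 1):
        bb, cc = row1 - aa, col1 - aa
        dd = row2 - cc
        p = hypergeom_table_prob(aa, bb, cc, dd)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def bh_step_up(pvals):
    """Benjamini-Hochberg step-up, spelled out."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return q
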