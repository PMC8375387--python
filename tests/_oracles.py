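"""Independent brute-force oracles used by the tests.

Everything here is implemented with explicit loops and elementary
arithmetic, sharing no code with the package, so equality against these
functions is a genuine cross-check.
"""

import itertools
import math


def faime_brute_force(values, sets_members):
    """Rank-weighted set scores by explicit per-sample loops.

    ``values``: DataFrame genes x samples.  ``sets_members``: name -> list of
    genes.  Returns {set: {sample: score}}.
    """
    genes = list(values.index)
    N = len(genes)
    out = {name: {} for name in sets_members}
    for sample in values.columns:
        col = values[sample]
        order = sorted(genes, key=lambda g: -col[g])
        ranks = {}
        i = 0
        while i < len(order):
            j = i
            while j < len(order) and col[order[j]] == col[order[i]]:
                j += 1
            avg = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
            for t in range(i, j):
                ranks[order[t]] = avg
            i = j
        weights = {g: col[g] * math.exp(-(ranks[g] - 1.0) / N) for g in genes}
        for name, members in sets_members.items():
            mem = [g for g in members if g in weights]
            mem_set = set(mem)
            non = [g for g in genes if g not in mem_set]
            score = sum(weights[g] for g in mem) / len(mem) - sum(
                weights[g] for g in non
            ) / len(non)
            out[name][sample] = score
    return out


def hypergeom_tail_exact(N, K, n, k):
    """P[X >= k] by exact integer enumeration of draws grouped by overlap count."""
    total = math.comb(N, n)
    hits = 0
    for j in range(max(k, 0), min(K, n) + 1):
        hits += math.comb(K, j) * math.comb(N - K, n - j)
    return hits / total


def hypergeom_tail_draws(N, K, n, k):
    """P[X >= k] by literal enumeration of all C(N, n) subset draws."""
    special = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def auc_pair_count(control, condition):
    """AUC by exhaustive pair counting; ties count one half."""
    wins = 0.0
    for c in condition:
        for b in control:
            if c > b:
                wins += 1.0
            elif c == b:
                wins += 0.5
    return wins / (len(control) * len(condition))


def bh_stepup(p):
    """Benjamini-Hochberg step-up by direct evaluation; output in input order."""
    m = len(p)
    idx = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = idx[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def pooled_t(x1, x2):
    """Classical equal-variance two-sample t statistic (x2 minus x1), by hand."""
    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
    sp2 = ss / (n1 + n2 - 2)
    return (m2 - m1) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
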