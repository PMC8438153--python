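"""Independent brute-force oracles used to check the implementations.

These are deliberately naive (loops, enumeration, closed forms) and share no
code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ssgsea_brute(values: np.ndarray, gene_names: list[str], gene_set: set[str], alpha: float) -> float:
    """Position-by-position running-sum ES for one sample, recomputed naively."""
    n = len(values)
    # midranks (ascending), computed by hand
    order_vals = sorted(values)
    stat = np.empty(n)
    for i, v in enumerate(values):
        lo = order_vals.index(v) + 1
        hi = n - order_vals[::-1].index(v)
        stat[i] = (lo + hi) / 2
    # descending walk with stable index tie-break
    walk = sorted(range(n), key=lambda i: (-values[i], i))
    in_set = [gene_names[i] in gene_set for i in walk]
    w = [abs(stat[i]) ** alpha if gene_names[i] in gene_set else 0.0 for i in walk]
    wsum = sum(w)
    n_out = n - sum(in_set)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos in range(n):
        cum_in += w[pos] / wsum
        if not in_set[pos]:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def logrank_brute(times, events, groups) -> float:
    """Two-group log-rank chi-square via the hypergeometric sums at event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    lvls = sorted(set(groups.tolist()))
    assert len(lvls) == 2
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == lvls[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == lvls[0])).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def km_survival_brute(times, events) -> dict[float, float]:
    """Product-limit estimate at each event time, by hand."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out[float(t)] = s
    return out


def fisher_brute(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def ranksum_all_assignments(values, n1: int):
    """All rank sums of the first group over every assignment of labels."""
    values = np.asarray(values, float)
    ranks = np.argsort(np.argsort(values)) + 1.0
    idx = range(len(values))
    sums = [ranks[list(comb)].sum() for comb in itertools.combinations(idx, n1)]
    return sums


def pearson_brute(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    return float(((x - mx) * (y - my)).sum() / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))


def bh_brute(p):
    """Step-up BH by hand."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj
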