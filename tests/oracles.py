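"""Independent brute-force oracles: textbook formulas and O(n^3) enumeration,
deliberately written without numpy vectorization or the library calls the
implementation uses."""

from __future__ import annotations

import math


def pearson_brute(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def cv_brute(x) -> float:
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    return math.sqrt(var) / abs(mean)


def zscores_brute(x) -> list[float]:
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)  # population SD
    return [(v - mean) / sd for v in x]


def average_linkage_heights_brute(points) -> list[float]:
    """Merge heights of agglomerative average-linkage clustering, O(n^3).

    Cluster distance = mean pairwise Euclidean distance between members.
    Returns the n-1 merge heights in merge order.
    """

    def dist(a, b):
        return math.sqrt(sum((u - v) ** 2 for u, v in zip(a, b)))

    clusters = [[tuple(p)] for p in points]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = sum(dist(a, b) for a in clusters[i] for b in clusters[j]) / (
                    len(clusters[i]) * len(clusters[j])
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


def consensus_brute(sets_by_db: dict, min_databases: int) -> dict:
    """gene -> sorted supporting dbs, for genes in >= min_databases sets."""
    genes = set()
    for s in sets_by_db.values():
        genes |= set(s)
    out = {}
    for g in sorted(genes):
        dbs = sorted(db for db, s in sets_by_db.items() if g in s)
        if len(dbs) >= min_databases:
            out[g] = dbs
    return out


def venn_brute(sets_by_db: dict) -> dict:
    """Exclusive region counts keyed by sorted tuple of database names."""
    from itertools import combinations

    names = sorted(sets_by_db)
    genes = set()
    for s in sets_by_db.values():
        genes |= set(s)
    counts = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[combo] = 0
    for g in genes:
        member = tuple(n for n in names if g in sets_by_db[n])
        counts[member] += 1
    return counts


def km_brute(times, events) -> dict:
    """Product-limit estimate: {event time: S(t)}, deaths before censorings."""
    n = len(times)
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    surv = {}
    s = 1.0
    for t in distinct:
        at_risk = sum(1 for ti in times if ti >= t)
        deaths = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1.0 - deaths / at_risk
        surv[t] = s
    return surv


def logrank_chi2_brute(t1, e1, t2, e2) -> float:
    """Unweighted two-group log-rank chi-square: (sum O - sum E)^2 / sum V."""
    all_event_times = sorted({t for t, e in zip(list(t1) + list(t2), list(e1) + list(e2)) if e == 1})
    O = E = V = 0.0
    for t in all_event_times:
        n1 = sum(1 for ti in t1 if ti >= t)
        n2 = sum(1 for ti in t2 if ti >= t)
        n = n1 + n2
        d1 = sum(1 for ti, ei in zip(t1, e1) if ti == t and ei == 1)
        d2 = sum(1 for ti, ei in zip(t2, e2) if ti == t and ei == 1)
        d = d1 + d2
        if n < 2:
            continue
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V
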