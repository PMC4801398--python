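"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package implementations they
check: the GSEA running sum is a literal position-by-position walk, the
moderated t re-derives the empirical-Bayes shrinkage from its definition,
and Ward.D2 is a naive Lance-Williams agglomeration.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def brute_force_es(scores: pd.Series, genes, weight: float = 1.0) -> float:
    """Literal walk down the ranked list, evaluating the running sum at
    every position as (cumulative hit weight) - (miss count) * step."""
    members = set(genes)
    hit_weight_total = sum(
        abs(s) ** weight for g, s in scores.items() if g in members
    )
    n_hits = sum(g in members for g in scores.index)
    step = 1.0 / (len(scores) - n_hits)
    cum_hits = 0.0
    n_miss = 0
    best = 0.0
    for g, s in scores.items():
        if g in members:
            if hit_weight_total > 0:
                cum_hits += abs(s) ** weight / hit_weight_total
            else:
                cum_hits += 1.0 / n_hits
        else:
            n_miss += 1
        running = cum_hits - n_miss * step
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def brute_force_moderated_t(
    matrix: pd.DataFrame, vector_cols, control_cols
) -> pd.Series:
    """Empirical-Bayes moderated t recomputed from the definition.

    Moment-matching of log sample variances against the log-F
    distribution, solved by bisection on the trigamma equation.
    """
    from scipy.special import digamma, polygamma

    v = matrix[list(vector_cols)].to_numpy(float)
    c = matrix[list(control_cols)].to_numpy(float)
    n1, n2 = v.shape[1], c.shape[1]
    dg = n1 + n2 - 2
    diff = v.mean(1) - c.mean(1)
    s2 = (((v.T - v.mean(1)).T ** 2).sum(1) + ((c.T - c.mean(1)).T ** 2).sum(1)) / dg
    s2 = np.maximum(s2, 1e-5 * np.median(s2) if np.median(s2) > 0 else 1.0)
    e = np.log(s2) - digamma(dg / 2) + math.log(dg / 2)
    evar = e.var(ddof=1) - polygamma(1, dg / 2)
    if evar > 0:
        # bisection for trigamma(d0/2) = evar
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2 * math.sqrt(lo * hi)
        s02 = math.exp(e.mean() + digamma(d0 / 2) - math.log(d0 / 2))
        stilde2 = (d0 * s02 + dg * s2) / (d0 + dg)
    else:
        stilde2 = np.full_like(s2, s2.mean())
    t = diff / np.sqrt(stilde2 * (1 / n1 + 1 / n2))
    return pd.Series(t, index=matrix.index)


def brute_force_ward_d2(points: np.ndarray, k: int) -> list[set[int]]:
    """Naive Ward.D2 agglomeration via the Lance-Williams recurrence."""
    points = np.asarray(points, float).reshape(len(points), -1)
    clusters = {i: {i} for i in range(len(points))}
    dist = {}
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            dist[(i, j)] = float(np.linalg.norm(points[i] - points[j]))

    def d(a, b):
        return dist[(min(a, b), max(a, b))]

    next_id = len(points)
    while len(clusters) > k:
        (a, b) = min(
            ((x, y) for x in clusters for y in clusters if x < y), key=lambda p: d(*p)
        )
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) | clusters.pop(b)
        for c in list(clusters):
            nc = len(clusters[c])
            dd = math.sqrt(
                ((na + nc) * d(a, c) ** 2 + (nb + nc) * d(b, c) ** 2 - nc * d(a, b) ** 2)
                / (na + nb + nc)
            )
            dist[(min(c, next_id), max(c, next_id))] = dd
        clusters[next_id] = merged
        next_id += 1
    return list(clusters.values())
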