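"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorized code paths (and the scipy calls)
they validate: plain loops, enumeration and closed forms only.
"""

from __future__ import annotations

import itertools
import math

from sectorloh.model import Genotype


def nearest_centroid_oracle(w: float, h: float, max_distance: float = 0.45) -> Genotype:
    """Loop-based nearest-centroid call with tie -> UNCALLED."""
    cents = [
        (Genotype.HET, 1.0, 1.0),
        (Genotype.HOM_W, 1.6, 0.3),
        (Genotype.HOM_Y, 0.3, 1.6),
    ]
    dists = [(math.hypot(w - cw, h - cy), g) for g, cw, cy in cents]
    dists.sort(key=lambda t: t[0])
    if dists[0][0] > max_distance or dists[0][0] == dists[1][0]:
        return Genotype.UNCALLED
    return dists[0][1]


def runs_oracle(states):
    """Reference run-length segmentation with uncalled absorption."""
    absorbable = {Genotype.UNCALLED, Genotype.HEMIZYGOUS_LOSS}
    called = [s for s in states if s not in absorbable]
    if not called:
        return [(Genotype.UNCALLED, 0, len(states) - 1)] if states else []
    eff = []
    last = None
    first_called = next(s for s in states if s not in absorbable)
    for s in states:
        if s in absorbable:
            eff.append(last if last is not None else first_called)
        else:
            eff.append(s)
            last = s
    runs = []
    start = 0
    for i in range(1, len(eff) + 1):
        if i == len(eff) or eff[i] != eff[start]:
            runs.append((Genotype(eff[start]), start, i - 1))
            start = i
    return runs


def mw_exact_oracle(a, b):
    """Exact two-sided Mann-Whitney p by enumeration of rank arrangements."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n, m = len(a), len(b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n * (n + 1) // 2
    dist = {}
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) // 2
        dist[u] = dist.get(u, 0) + 1
    total = sum(dist.values())
    cdf = sum(c for u, c in dist.items() if u <= u_obs) / total
    sf = sum(c for u, c in dist.items() if u >= u_obs) / total
    return u_obs, min(1.0, 2 * min(cdf, sf))


def exhaustive_placement_pvalue(span_len: int, elements, arm) -> dict[int, float]:
    """Exact null distribution of the overlap count for ONE placed span.

    Enumerates every integer start on the arm; returns P(count >= c) for
    each achievable count c.
    """
    lo, hi = arm
    counts = []
    for start in range(lo, hi - span_len + 1):
        end = start + span_len
        c = sum(1 for s, e in elements if s <= end and e >= start)
        counts.append(c)
    out = {}
    for c in set(counts):
        out[c] = sum(1 for x in counts if x >= c) / len(counts)
    return out


def chi2_gof_oracle(observed, lengths):
    """Textbook chi-square GOF statistic with expectations from lengths."""
    n = sum(observed)
    tot = sum(lengths)
    chi2 = 0.0
    for o, ln in zip(observed, lengths):
        e = n * ln / tot
        chi2 += (o - e) ** 2 / e
    return chi2


def step_up_fdr_oracle(pvals):
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
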