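"""Independent reference implementations used only as test oracles.

Everything here is written straight from the defining formulas with
plain Python loops — deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations

from scipy.integrate import quad


def biweight_transform_oracle(v: list[float]) -> list[float]:
    med = statistics.median(v)
    d = [x - med for x in v]
    mad = statistics.median([abs(x) for x in d])
    if mad == 0:
        mean = sum(v) / len(v)
        c = [x - mean for x in v]
        norm = math.sqrt(sum(x * x for x in c))
        return [x / norm for x in c]
    num = []
    for di in d:
        u = di / (9.0 * mad)
        w = (1.0 - u * u) ** 2 if abs(u) < 1.0 else 0.0
        num.append(di * w)
    norm = math.sqrt(sum(x * x for x in num))
    if norm == 0:  # every off-median point beyond the biweight window
        mean = sum(v) / len(v)
        c = [x - mean for x in v]
        norm = math.sqrt(sum(x * x for x in c))
        return [x / norm for x in c]
    return [x / norm for x in num]


def bicor_oracle(x: list[float], y: list[float]) -> float:
    a = biweight_transform_oracle(list(x))
    b = biweight_transform_oracle(list(y))
    r = sum(ai * bi for ai, bi in zip(a, b))
    return max(-1.0, min(1.0, r))


def pearson_oracle(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def t_cdf_upper_oracle(t: float, df: int) -> float:
    """Upper tail of Student t by numerical integration of the density."""

    def density(u: float) -> float:
        c = math.exp(
            math.lgamma((df + 1) / 2.0)
            - math.lgamma(df / 2.0)
            - 0.5 * math.log(df * math.pi)
        )
        return c * (1.0 + u * u / df) ** (-(df + 1) / 2.0)

    val, _err = quad(density, t, math.inf)
    return val


def bicor_pvalue_oracle(r: float, n: int) -> float:
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * t_cdf_upper_oracle(t, n - 2)


def bh_oracle(pvals: list[float]) -> list[float]:
    """Quadratic-time BH step-up: q_i = min over j with p_j >= p_i of
    p_j * m / rank(p_j), computed by brute force."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    ranks = {}
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    q = [0.0] * m
    for i in range(m):
        candidates = []
        for j in range(m):
            if ranks[j] >= ranks[i]:
                candidates.append(pvals[j] * m / ranks[j])
        q[i] = min(1.0, min(candidates))
    return q


def running_es_oracle(weights: list[float], is_hit: list[bool]) -> float:
    """O(N * |S|) literal running sum of the weighted KS statistic."""
    n = len(weights)
    s = sum(is_hit)
    hit_total = sum(abs(w) for w, h in zip(weights, is_hit) if h)
    miss_inc = 1.0 / (n - s) if n != s else 0.0
    running = 0.0
    best = 0.0
    for w, h in zip(weights, is_hit):
        if h:
            running += abs(w) / hit_total if hit_total > 0 else 0.0
        else:
            running -= miss_inc
        if abs(running) > abs(best) or (
            abs(running) == abs(best) and running > best
        ):
            best = running
    return best


def hypergeom_p_oracle(universe: list[str], members: set[str], draw_size: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all draws."""
    total = 0
    exceed = 0
    for draw in combinations(universe, draw_size):
        total += 1
        if len(set(draw) & members) >= k:
            exceed += 1
    return exceed / total


def gsea_p_oracle(weights: list[float], set_size: int, observed_es: float) -> float:
    """Exact sign-stratified permutation p by enumerating every same-size
    membership assignment over the ranked universe."""
    n = len(weights)
    same_sign = 0
    exceed = 0
    for pos in combinations(range(n), set_size):
        hits = [i in pos for i in range(n)]
        es = running_es_oracle(weights, hits)
        if observed_es > 0 and es > 0 or observed_es < 0 and es < 0:
            same_sign += 1
            if abs(es) >= abs(observed_es):
                exceed += 1
    return exceed / same_sign if same_sign else 1.0
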