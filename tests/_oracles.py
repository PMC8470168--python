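"""Independent brute-force oracles, kept deliberately separate from the package.

Everything here is coded from first principles (rational arithmetic where
feasible, naive enumeration elsewhere) so the test suite checks the package
against a second, independent route.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def oracle_knn_predict(store, query_vec, query_id, k, metric="manhattan", weighting="inverse"):
    """Exhaustive-scan KNN with exact rational weighting (Manhattan path).

    ``store``: iterable of (product_id, feature list, fiber).  Returns
    (predicted_fiber, d1, ordered neighbor ids).
    """
    rows = []
    for pid, vec, fib in store:
        if pid == query_id:
            continue
        if metric == "manhattan":
            d = sum(abs(Fraction(a) - Fraction(b)) for a, b in zip(vec, query_vec))
        else:
            d = Fraction(math.sqrt(sum((a - b) ** 2 for a, b in zip(vec, query_vec))))
        rows.append((d, pid, Fraction(fib)))
    rows.sort(key=lambda r: (r[0], r[1]))
    sel = rows[: min(k, len(rows))]
    zeros = [f for d, _, f in sel if d == 0]
    if zeros:
        q = sum(zeros) / len(zeros)
    elif weighting == "uniform":
        q = sum(f for _, _, f in sel) / len(sel)
    else:
        wsum = sum(Fraction(1) / d for d, _, _ in sel)
        q = sum(f / d for d, _, f in sel) / wsum
    return float(q), float(sel[0][0]), [p for _, p, _ in sel]


def oracle_manhattan(x, y):
    return float(sum(abs(Fraction(a) - Fraction(b)) for a, b in zip(x, y)))


def oracle_r2(y, yhat):
    y = [Fraction(v) for v in y]
    yhat = [Fraction(v) for v in yhat]
    mean = sum(y) / len(y)
    ss_tot = sum((v - mean) ** 2 for v in y)
    ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
    return float(1 - ss_res / ss_tot)


def oracle_mae(y, yhat):
    return float(sum(abs(Fraction(a) - Fraction(b)) for a, b in zip(y, yhat)) / len(y))


def _ranks(values):
    """Average ranks for ties, 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def oracle_spearman(y, yhat):
    """Pearson correlation of tie-averaged ranks, from the textbook formula."""
    ry, rp = _ranks(list(y)), _ranks(list(yhat))
    n = len(ry)
    my, mp = sum(ry) / n, sum(rp) / n
    num = sum((a - my) * (b - mp) for a, b in zip(ry, rp))
    den = math.sqrt(sum((a - my) ** 2 for a in ry) * sum((b - mp) ** 2 for b in rp))
    return num / den


def oracle_ranksum_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration (no ties allowed).

    Counts the group assignments whose U statistic is at least as extreme, on
    either tail, as the observed one.
    """
    pooled = list(a) + list(b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    m = n1 * len(b)
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    n_extreme = total = 0
    for idx in combinations(range(len(pooled)), n1):
        chosen = set(idx)
        av = [pooled[i] for i in idx]
        bv = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = sum(1 for x in av for y in bv if x > y)
        total += 1
        if u <= lo or u >= hi:
            n_extreme += 1
    return n_extreme / total


def oracle_percentile(values, q):
    """Linear-interpolation percentile between order statistics."""
    xs = sorted(values)
    if len(xs) == 1:
        return float(xs[0])
    pos = (len(xs) - 1) * q / 100
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return float(xs[lo] * (1 - frac) + xs[hi] * frac)


def oracle_median_iqr(values):
    return (
        oracle_percentile(values, 50),
        oracle_percentile(values, 75) - oracle_percentile(values, 25),
    )
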