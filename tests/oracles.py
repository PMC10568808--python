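"""Independent brute-force oracles used to validate the analysis implementations.

These deliberately avoid the library code paths (and scipy's tests): exact
p-values come from full enumeration, enrichment from naive double loops.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Sequence


def mann_whitney_exact_p(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Exact Mann-Whitney p by enumerating all group assignments of the pooled data."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in xs for yi in ys
        )

    observed = u_stat(x, y)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        cset = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in cset]
        us.append(u_stat(xs, ys))
    total = len(us)
    eps = 1e-9
    p_ge = sum(1 for u in us if u >= observed - eps) / total
    p_le = sum(1 for u in us if u <= observed + eps) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def fisher_two_sided_p(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by summing hypergeometric outcomes as or less likely."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k: int) -> float:
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    p_obs = pmf(a)
    return min(
        1.0,
        sum(pmf(k) for k in range(k_min, k_max + 1) if pmf(k) <= p_obs * (1 + 1e-9)),
    )


def fold_enrichment_naive(pairs, standard, background):
    """Naive double-loop fold enrichment: related fraction ratio on available pairs."""
    obs_av = [p for p in pairs if standard.available(p[0], p[1])]
    bg_av = [p for p in background if standard.available(p[0], p[1])]
    obs_rel = [p for p in obs_av if standard.related(p[0], p[1])]
    bg_rel = [p for p in bg_av if standard.related(p[0], p[1])]
    if not bg_rel:
        return math.inf if obs_rel else math.nan
    return (len(obs_rel) / len(obs_av)) / (len(bg_rel) / len(bg_av))


def comutation_counts_naive(pairs, matrix) -> dict:
    """Per-pair co-mutation counts by an explicit per-sample AND-then-sum loop."""
    out = {}
    for q, s in pairs:
        if q not in matrix.index or s not in matrix.index:
            continue
        count = 0
        for col in matrix.columns:
            if bool(matrix.at[q, col]) and bool(matrix.at[s, col]):
                count += 1
        out[(q, s)] = count
    return out
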