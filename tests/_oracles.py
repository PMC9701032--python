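"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit enumeration over expanded
reads, substrings, permutations or subsets, with no code shared with the
package under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def metric_oracle(haps: list[tuple[int, str, int]], n_cpgs: int) -> dict[str, float]:
    """All seven block measurements by explicit enumeration.

    ``haps`` is a list of (first_cpg_index, pattern, count); every record is
    expanded into ``count`` identical reads and every substring of every
    read is enumerated one by one.
    """
    reads: list[tuple[int, str]] = []
    for offset, pattern, count in haps:
        reads.extend([(offset, pattern)] * count)

    nan = float("nan")
    if not reads:
        return {m: nan for m in
                ("amf", "mhl", "mhl3", "umhl", "umhl3", "mhfm", "mhfu")}

    meth_obs = sum(p.count("1") for _, p in reads)
    total_obs = sum(len(p) for _, p in reads)
    amf = meth_obs / total_obs

    p_meth: dict[int, float] = {}
    p_unmeth: dict[int, float] = {}
    for i in range(1, n_cpgs + 1):
        total = meth = unmeth = 0
        for _, pattern in reads:
            for j in range(len(pattern) - i + 1):
                sub = pattern[j : j + i]
                total += 1
                if sub == "1" * i:
                    meth += 1
                if sub == "0" * i:
                    unmeth += 1
        if total > 0:
            p_meth[i] = meth / total
            p_unmeth[i] = unmeth / total

    def load(p: dict[int, float], power: int) -> float:
        if not p:
            return nan
        wsum = sum(i**power for i in p)
        return sum((i**power) * v for i, v in p.items()) / wsum

    full = [(o, p) for o, p in reads if o == 0 and len(p) == n_cpgs]
    if full:
        mhfm = sum(1 for _, p in full if p == "1" * n_cpgs) / len(full)
        mhfu = sum(1 for _, p in full if p == "0" * n_cpgs) / len(full)
    else:
        mhfm = mhfu = nan

    return {"amf": amf, "mhl": load(p_meth, 1), "mhl3": load(p_meth, 3),
            "umhl": load(p_unmeth, 1), "umhl3": load(p_unmeth, 3),
            "mhfm": mhfm, "mhfu": mhfu}


def exact_rank_sum_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration (no ties)."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in x)
    n, m = len(x), len(y)
    mean = n * (len(pooled) + 1) / 2
    dev = abs(observed - mean)
    count = 0
    total = 0
    all_ranks = list(range(1, len(pooled) + 1))
    for subset in combinations(all_ranks, n):
        total += 1
        if abs(sum(subset) - mean) >= dev - 1e-9:
            count += 1
    return count / total


def auc_pair_counting(scores: list[float], labels: list[int]) -> float:
    """AUC by exhaustive positive/negative pair comparison with tie credit."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def hypergeom_upper_tail(k: int, universe: int, n_reference: int, n_panel: int) -> float:
    """P(overlap >= k) by summing the exact hypergeometric pmf."""
    total = comb(universe, n_panel)
    acc = 0
    for j in range(k, min(n_reference, n_panel) + 1):
        acc += comb(n_reference, j) * comb(universe - n_reference, n_panel - j)
    return acc / total


def pair_r2(n11: int, n10: int, n01: int, n00: int) -> float:
    """LD r^2 from a 2x2 table, by the textbook haplotype-frequency formula."""
    n = n11 + n10 + n01 + n00
    p11, p1_, p_1 = n11 / n, (n11 + n10) / n, (n11 + n01) / n
    d = p11 - p1_ * p_1
    return d * d / (p1_ * (1 - p1_) * p_1 * (1 - p_1))
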