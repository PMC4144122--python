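"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths (and where possible the libraries)
they check: the Fisher oracle enumerates the hypergeometric distribution with
``math.comb``; the rank-sum oracle counts pairwise wins instead of ranks.
"""

from __future__ import annotations

import math
from itertools import combinations


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums, over all 2x2 tables with the observed margins, the probabilities not
    exceeding the observed table's probability ("sum of small p" rule).
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def ranksum_permutation_oracle(a, b) -> float:
    """Two-sided Mann-Whitney p by enumerating every group labeling.

    The U statistic is computed from pairwise comparisons (wins + half-ties),
    not from ranks, to stay independent of the implementation under test.
    """
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(idx_a) -> float:
        in_a = set(idx_a)
        u = 0.0
        for i in idx_a:
            for j in range(len(pooled)):
                if j in in_a:
                    continue
                if pooled[i] > pooled[j]:
                    u += 1.0
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    mean_u = n_a * (len(pooled) - n_a) / 2
    obs = abs(u_of(range(n_a)) - mean_u)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        if abs(u_of(idx) - mean_u) >= obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def revcomp_str(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))
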