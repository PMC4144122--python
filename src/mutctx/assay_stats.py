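"""Small-sample statistics for the wet-lab readouts.

Three analyses share this module: fluctuation assays (parallel independent
overnight cultures scored for resistant colonies, summarised as per-culture
mutation frequency resistant/plated and the per-construct median), two-group
comparison of small sets of fractions by an exact Mann-Whitney rank-sum test,
and reference-gene-normalised expression comparison across sample groups
(log2 ratio to a housekeeping gene such as TBP, median-centred, one-way ANOVA
with Tukey HSD post-hoc).

Mutation *frequency*, not mutation rate: no Luria-Delbrueck fluctuation-rate
estimator is applied; the assays are summarised exactly as plated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: combined sample size up to which the rank-sum p is computed by exact
#: enumeration of all label assignments (handles ties without approximation)
EXACT_RANKSUM_LIMIT = 20


@dataclass
class FluctuationAssay:
    """Per-culture resistant-colony counts from a fluctuation experiment."""

    cultures: pd.DataFrame  # columns: culture_id, construct, resistant, plated

    REQUIRED = ("culture_id", "construct", "resistant", "plated")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.cultures.columns]
        if missing:
            raise ValueError(f"missing column(s) {missing}")
        df = self.cultures
        if (df["plated"] <= 0).any():
            raise ValueError("plated_count must be positive")
        if (df["resistant"] < 0).any() or (df["resistant"] > df["plated"]).any():
            raise ValueError("resistant_count must be in [0, plated_count]")

    @property
    def frequencies(self) -> pd.Series:
        return self.cultures["resistant"] / self.cultures["plated"]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression intensities with group labels."""

    data: pd.DataFrame  # genes x samples, nonnegative intensities
    groups: dict[str, str]  # sample -> group
    ref_gene: str = "TBP"

    def __post_init__(self) -> None:
        if self.ref_gene not in self.data.index:
            raise ValueError(f"reference gene {self.ref_gene!r} absent from matrix")
        if (self.data.loc[self.ref_gene] <= 0).any():
            raise ValueError(f"reference gene {self.ref_gene!r} has nonpositive values")
        unknown = set(self.data.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without group label: {sorted(unknown)}")


def mutation_frequencies(
    assay: FluctuationAssay,
) -> dict[str, tuple[list[float], float]]:
    """Per-construct culture frequencies and their median.

    Median uses the midpoint convention for even numbers of cultures.
    """
    out: dict[str, tuple[list[float], float]] = {}
    df = assay.cultures.assign(freq=assay.frequencies)
    for construct, sub in df.groupby("construct", sort=False):
        freqs = sub["freq"].tolist()
        out[str(construct)] = (freqs, float(np.median(freqs)))
    return out


def _ranksum_u(values: np.ndarray, idx_a: Sequence[int], n_a: int) -> float:
    ranks = stats.rankdata(values)  # midranks for ties
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2)


def exact_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration of labelings.

    Counts, over all C(n_a+n_b, n_a) assignments of the pooled values to the
    two groups, the fraction with |U - n_a n_b / 2| at least the observed
    deviation.  Midranks make the enumeration valid in the presence of ties.
    """
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n_a, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2
    mean_u = n_a * (n - n_a) / 2
    obs_dev = abs(ranks[:n_a].sum() - offset - mean_u)
    hits = total = 0
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mean_u) >= obs_dev - 1e-9:
            hits += 1
        total += 1
    return hits / total


def compare_groups_rank(
    a: Sequence[float], b: Sequence[float]
) -> dict[str, float | str]:
    """Two-sided Mann-Whitney rank-sum comparison of two small groups.

    Exact enumeration when the combined sample size is at most
    ``EXACT_RANKSUM_LIMIT``; the normal approximation with tie correction
    otherwise.  Returns medians, the U statistic for the first group, the
    p-value and the method used.
    """
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.asarray(list(a) + list(b), dtype=float)
    ranks = stats.rankdata(pooled)
    u = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)
    if len(pooled) <= EXACT_RANKSUM_LIMIT:
        p = exact_ranksum_p(a, b)
        method = "exact"
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
        method = "normal_approx_tie_corrected"
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "U": u,
        "p": p,
        "method": method,
    }


def normalize_expression(
    m: ExpressionMatrix, gene: str, pseudocount: float = 0.0
) -> pd.Series:
    """Reference-gene-normalised, median-centred log2 values for one gene.

    v_i = log2(x_i / ref_i), then centred on the median across samples, so the
    output median is 0 and the values are invariant to rescaling any sample's
    whole column.  Nonpositive gene values raise by default; pass a positive
    ``pseudocount`` to add to the gene values instead.
    """
    if gene not in m.data.index:
        raise ValueError(f"gene {gene!r} absent from matrix")
    x = m.data.loc[gene].astype(float) + pseudocount
    if (x <= 0).any():
        raise ValueError(
            f"gene {gene!r} has nonpositive values; supply a pseudocount to proceed"
        )
    v = np.log2(x / m.data.loc[m.ref_gene].astype(float))
    return v - v.median()


def anova_tukey(
    values: pd.Series | Mapping[str, float], groups: Mapping[str, str]
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across groups with Tukey HSD post-hoc.

    ``values`` maps sample -> value, ``groups`` maps sample -> group label.
    Returns (F, p, table) where the table holds one row per group pair with
    the mean difference and the Tukey-adjusted p.  All-identical values leave
    F undefined and raise.
    """
    values = pd.Series(values)
    labels = sorted({groups[s] for s in values.index})
    arrays = [values[[s for s in values.index if groups[s] == g]].to_numpy() for g in labels]
    if len(arrays) < 2 or any(len(arr) < 2 for arr in arrays):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        raise ValueError("all values identical; F statistic undefined")
    if all(np.allclose(arr.mean(), arrays[0].mean()) for arr in arrays) and all(
        np.var(arr) == 0 for arr in arrays
    ):
        # equal means, zero within-group variance: F = 0/0
        raise ValueError("zero variance everywhere; F statistic undefined")
    f_stat, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        ci = hsd.confidence_interval()
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(hsd.pvalue[i, j]),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
            }
        )
    return float(f_stat), float(p), pd.DataFrame(rows)
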