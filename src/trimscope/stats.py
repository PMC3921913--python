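"""Rank-based comparison of HSP-ratio distributions across read treatments.

Implements the tie-corrected Kruskal–Wallis one-way analysis of variance
and the Conover rank-LSD post hoc procedure (t-quantile on mean-rank
differences with the pooled-rank variance and (N-1-H)/(N-k) shrinkage, no
multiple-testing adjustment), followed by compact-letter display: groups
ordered by descending mean rank share a letter iff their pairwise
comparison is non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupData:
    label: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError(f"group {self.label!r} is empty")


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p: float


@dataclass(frozen=True)
class PairComparison:
    label_a: str
    label_b: str
    mean_rank_diff: float
    critical_difference: float
    significant: bool


@dataclass(frozen=True)
class PosthocResult:
    labels: list[str]
    mean_ranks: dict[str, float]
    pairs: list[PairComparison]
    letters: dict[str, str]
    alpha: float

    def significant(self, a: str, b: str) -> bool:
        for pc in self.pairs:
            if {pc.label_a, pc.label_b} == {a, b}:
                return pc.significant
        raise KeyError(f"no comparison for {a!r} vs {b!r}")


def rank_with_ties(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..N with tied values receiving the mean of the spanned ranks."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty sequence")
    return sps.rankdata(values, method="average")


def _as_groups(groups) -> list[GroupData]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupData):
            out.append(g)
        elif isinstance(g, tuple) and len(g) == 2 and isinstance(g[0], str):
            out.append(GroupData(g[0], np.asarray(g[1], dtype=float)))
        else:
            out.append(GroupData(f"group{i}", np.asarray(g, dtype=float)))
    return out


def _pooled_ranks(groups: list[GroupData]):
    pooled = np.concatenate([g.values for g in groups])
    ranks = rank_with_ties(pooled)
    sizes = [g.values.size for g in groups]
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    return pooled, ranks, split


def kruskal_wallis(groups) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H with chi-square upper-tail p-value.

    H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / [1 - sum(t^3 - t)/(N^3 - N)]
    with R_i the group rank sums and t the tie-block sizes; df = k - 1.
    If every pooled value is identical the statistic is defined as 0 (p=1).
    """
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    pooled, ranks, split = _pooled_ranks(groups)
    N = pooled.size
    h0 = 12.0 / (N * (N + 1)) * sum(r.sum() ** 2 / r.size for r in split) - 3.0 * (
        N + 1
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (N**3 - N)
    df = len(groups) - 1
    if correction <= 0.0:  # all pooled values identical
        return KruskalResult(0.0, df, 1.0)
    H = h0 / correction
    p = float(sps.chi2.sf(H, df))
    return KruskalResult(float(H), df, p)


def posthoc_rank_lsd(groups, alpha: float = 0.01) -> PosthocResult:
    """Conover's Fisher-LSD-on-ranks pairwise comparisons with letters.

    Groups i and j differ at level ``alpha`` iff

        |Rbar_i - Rbar_j| > t_{1-alpha/2, N-k}
            * sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))

    where S^2 is the variance of the pooled ranks and H the tie-corrected
    Kruskal–Wallis statistic. No multiple-testing p-adjustment is applied.
    """
    groups = _as_groups(groups)
    kw = kruskal_wallis(groups)
    pooled, ranks, split = _pooled_ranks(groups)
    N, k = pooled.size, len(groups)
    if N <= k:
        raise ValueError("need more observations than groups")
    s2 = (float(np.sum(ranks**2)) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    shrink = max(N - 1 - kw.H, 0.0) / (N - k)
    tcrit = float(sps.t.ppf(1 - alpha / 2.0, N - k))
    mean_ranks = {g.label: float(r.mean()) for g, r in zip(groups, split)}
    sizes = {g.label: g.values.size for g in groups}
    labels = [g.label for g in groups]
    pairs: list[PairComparison] = []
    sig: dict[frozenset, bool] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            diff = abs(mean_ranks[a] - mean_ranks[b])
            cd = tcrit * np.sqrt(s2 * shrink * (1.0 / sizes[a] + 1.0 / sizes[b]))
            significant = diff > cd
            pairs.append(PairComparison(a, b, diff, float(cd), significant))
            sig[frozenset((a, b))] = significant
    letters = assign_group_letters(mean_ranks, sig)
    return PosthocResult(labels, mean_ranks, pairs, letters, alpha)


def assign_group_letters(
    mean_ranks: dict[str, float], significant: dict
) -> dict[str, str]:
    """Compact-letter display via insert-and-absorb.

    ``significant`` maps unordered label pairs (frozenset or 2-tuple) to a
    boolean. Groups are ordered by descending mean rank (largest mean rank
    gets 'a'); two groups share at least one letter iff their comparison is
    non-significant.
    """
    sig = {frozenset(k): v for k, v in significant.items()}
    labels = sorted(mean_ranks, key=lambda l: (-mean_ranks[l], l))
    pos = {l: i for i, l in enumerate(labels)}

    def is_sig(a: str, b: str) -> bool:
        return sig.get(frozenset((a, b)), False)

    columns: list[set[str]] = [set(labels)]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            if not is_sig(a, b):
                continue
            new_columns: list[set[str]] = []
            for col in columns:
                if a in col and b in col:
                    new_columns.append(col - {a})
                    new_columns.append(col - {b})
                else:
                    new_columns.append(col)
            # absorb: drop empties, duplicates and strict subsets
            uniq: list[set[str]] = []
            for c in new_columns:
                if c and c not in uniq:
                    uniq.append(c)
            columns = [c for c in uniq if not any(c < d for d in uniq)]
    columns.sort(key=lambda c: min(pos[l] for l in c))
    letters = {l: "" for l in labels}
    for letter_index, col in enumerate(columns):
        ch = chr(ord("a") + letter_index)
        for l in labels:
            if l in col:
                letters[l] += ch
    return letters
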