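"""Carrier vs. non-carrier association statistics for intron retention.

Given per-sample intron-retention ratios split into carriers of an IRAV
(positive group) and non-carriers (negative group), this module computes:
a Z-value expressing the carrier effect in units of the background spread,
a permutation p-value on the carrier-group mean, a one-sided Wilcoxon
rank-sum p per tissue/group (alternative: carriers greater), and Fisher's
method to combine the per-group p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupedRatios:
    """Carrier (positive) and non-carrier (negative) retention ratios."""

    positive: tuple[float, ...]
    negative: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        if not self.positive:
            raise ValueError("positive group must be non-empty")


@dataclass(frozen=True)
class AssocResult:
    z: float
    perm_p: float
    per_group_p: tuple[float, ...]
    fisher_chi2: float
    fisher_df: int
    fisher_p: float
    seed: int | None = None


def z_value(groups: GroupedRatios, pooled: bool = False) -> float:
    """Carrier effect (mean difference) in units of the negative-group
    sample standard deviation (n-1); ``pooled`` switches to a Welch-style
    pooled spread.  A zero spread yields +/-inf for differing means, else 0.
    """
    neg = np.asarray(groups.negative, dtype=float)
    pos = np.asarray(groups.positive, dtype=float)
    if neg.size < 2:
        raise ValueError("need >= 2 negative samples")
    diff = float(pos.mean() - neg.mean())
    if np.all(neg == neg[0]) and (not pooled or pos.size == 1 or np.all(pos == pos[0])):
        # degenerate spread: sign-preserving sentinel
        gap = float(pos.mean() - neg[0])
        return 0.0 if gap == 0.0 else math.copysign(math.inf, gap)
    if pooled:
        sd = math.sqrt(
            neg.var(ddof=1) / neg.size + (pos.var(ddof=1) / pos.size if pos.size > 1 else 0.0)
        )
    else:
        sd = float(neg.std(ddof=1))
    if sd == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / sd


def permutation_test(
    groups: GroupedRatios, n_perm: int = 10000, seed: int | None = None
) -> float:
    """Permutation p-value for the carrier-group mean.

    Labels are permuted preserving group sizes.  When the number of distinct
    carrier-label assignments C(n, k) is at most ``n_perm`` the test
    enumerates them exhaustively (p = #{assignment mean >= observed} / total,
    the identity included); otherwise Monte-Carlo sampling with +1 smoothing
    keeps p strictly positive.
    """
    values = np.asarray(groups.positive + groups.negative, dtype=float)
    k = len(groups.positive)
    n = values.size
    if n < 2:
        raise ValueError("need at least two samples in total")
    observed = float(np.mean(values[:k]))
    n_assign = comb(n, k)
    if n_assign <= n_perm:
        count = 0
        for idx in combinations(range(n), k):
            if float(values[list(idx)].mean()) >= observed - 1e-12:
                count += 1
        return count / n_assign
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        if float(values[idx].mean()) >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


EXACT_WILCOXON_MAX_N = 10


def wilcoxon_one_sided(groups_per_tissue: Sequence[GroupedRatios]) -> list[float]:
    """One-sided Wilcoxon rank-sum p (carriers greater) per group.

    Exact null distribution when the smaller side has at most 10 samples
    and there are no ties; normal approximation with continuity and tie
    correction otherwise.  Groups with an empty side are skipped with a NaN.
    """
    out = []
    for grp in groups_per_tissue:
        if not grp.positive or not grp.negative:
            out.append(float("nan"))
            continue
        pos = np.asarray(grp.positive, dtype=float)
        neg = np.asarray(grp.negative, dtype=float)
        has_ties = len(np.unique(np.concatenate([pos, neg]))) < pos.size + neg.size
        small = min(pos.size, neg.size)
        method = "exact" if (small <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(pos, neg, alternative="greater", method=method)
        out.append(float(res.pvalue))
    return out


def fisher_combine(per_group_p: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(ln p) on 2k degrees of freedom.

    Zero p-values are rejected (the log diverges); floor them upstream.
    """
    ps = [p for p in per_group_p if not math.isnan(p)]
    if not ps:
        raise ValueError("no p-values to combine")
    for p in ps:
        if p <= 0.0 or p > 1.0:
            raise ValueError(
                f"p-values must be in (0, 1]; got {p} (floor zero p-values upstream)"
            )
    chi2 = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def associate(
    groups_per_tissue: Sequence[GroupedRatios],
    n_perm: int = 10000,
    seed: int | None = None,
    pooled_z: bool = False,
) -> AssocResult:
    """All association statistics for one variant.

    The Z-value and permutation test are computed on all groups combined;
    the Wilcoxon tests per group, combined with Fisher's method.
    """
    all_pos = tuple(x for g in groups_per_tissue for x in g.positive)
    all_neg = tuple(x for g in groups_per_tissue for x in g.negative)
    combined = GroupedRatios(positive=all_pos, negative=all_neg)
    per_group = wilcoxon_one_sided(groups_per_tissue)
    chi2, df, fisher_p = fisher_combine(per_group)
    return AssocResult(
        z=z_value(combined, pooled=pooled_z),
        perm_p=permutation_test(combined, n_perm=n_perm, seed=seed),
        per_group_p=tuple(per_group),
        fisher_chi2=chi2,
        fisher_df=df,
        fisher_p=fisher_p,
        seed=seed,
    )
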