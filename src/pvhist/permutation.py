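"""Correlation-preserving permutation null for histogram-level thresholds.

Row permutation destroys any association between the feature matrix and the
group labels while keeping each row intact, so the correlation structure
among features is preserved in every replicate.  Carrying out the original
test on permuted data therefore yields p-value histograms from the null
distribution *without* assuming independence among features — the
assumption behind the analytic binomial thresholds, and the one most often
violated in expression data.

Two schemes are provided: ``group_label`` relabels rows for independent
two-group designs, and ``sign_flip`` swaps the members of a pair for paired
designs (equivalent to randomly negating within-pair differences).  The
engine records, per replicate, the first-bin count (for the
higher-criticism threshold) and the maximum bin count (for the
quality-control threshold) and returns empirical percentiles of each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .feature_tests import DesignInfo, FeatureMatrix, TestFunction
from .histogram import BinningConfig, bin_pvalues

__all__ = [
    "PermutationPlan",
    "PermutationNullSummary",
    "count_distinct_assignments",
    "generate_null_histograms",
    "permutation_hc_threshold",
    "permutation_qc_threshold",
]


def count_distinct_assignments(
    scheme: str,
    n1: int | None = None,
    n2: int | None = None,
    k: int | None = None,
) -> int:
    """Number of distinct null assignments available to a two-sided test.

    ``group_label``: C(n1+n2, n1) ways to choose group 1, halved when
    n1 = n2 because swapping the labels gives the identical two-sided test.
    ``sign_flip``: 2^k sign vectors over k pairs, halved because a global
    flip gives the identical two-sided test.
    """
    if scheme == "group_label":
        if n1 is None or n2 is None or n1 < 1 or n2 < 1:
            raise ValueError("group_label scheme needs group sizes n1, n2 >= 1")
        total = math.comb(n1 + n2, n1)
        return total // 2 if n1 == n2 else total
    if scheme == "sign_flip":
        if k is None or k < 1:
            raise ValueError("sign_flip scheme needs pair count k >= 1")
        return 2 ** (k - 1)
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass(frozen=True)
class PermutationPlan:
    """How to draw null replicates.

    ``B`` is the requested replicate count; when the full set of distinct
    assignments is no larger than B the engine switches to exhaustive
    enumeration (every distinct assignment exactly once, no randomness
    consumed).  In sampled mode the observed (identity) assignment is
    excluded from the null set; exhaustive mode enumerates the complete
    distinct set.
    """

    scheme: str  # "group_label" | "sign_flip"
    B: int = 1000
    seed: int | None = None
    percentile: float = 0.95
    exhaustive: bool | None = None  # None = decide from distinct_available
    distinct_available: int | None = None  # filled in when the plan is resolved

    def __post_init__(self) -> None:
        if self.scheme not in ("group_label", "sign_flip"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.B < 1:
            raise ValueError(f"replicate count B must be >= 1, got {self.B}")
        if not 0.0 < self.percentile < 1.0:
            raise ValueError(f"percentile must lie in (0, 1), got {self.percentile}")

    @property
    def min_distinct_required(self) -> int:
        """Smallest distinct-assignment count at which the requested percentile
        is not simply the sample maximum (20 for the 95th percentile)."""
        return math.ceil(1.0 / (1.0 - self.percentile) - 1e-9)


@dataclass(frozen=True)
class PermutationNullSummary:
    """Per-replicate first-bin and max-bin counts with derived thresholds."""

    first_bin_counts: np.ndarray
    max_bin_counts: np.ndarray
    hc_threshold_perm: float
    qc_threshold_perm: float
    percentile: float
    plan: PermutationPlan

    @property
    def B(self) -> int:
        return int(self.first_bin_counts.size)


def _percentile(counts: np.ndarray, percentile: float) -> float:
    # linear interpolation between order statistics
    return float(np.percentile(counts, percentile * 100.0, method="linear"))


def permutation_hc_threshold(summary: PermutationNullSummary) -> float:
    """Correlation-adjusted HC threshold: percentile of first-bin null counts."""
    return _percentile(summary.first_bin_counts, summary.percentile)


def permutation_qc_threshold(summary: PermutationNullSummary) -> float:
    """Correlation-adjusted QC threshold: percentile of max-bin null counts."""
    return _percentile(summary.max_bin_counts, summary.percentile)


def _unrank_combination(rank: int, n: int, k: int) -> tuple[int, ...]:
    """Lexicographic unranking of a k-subset of range(n)."""
    out = []
    start = 0
    for slot in range(k, 0, -1):
        for v in range(start, n - slot + 1):
            block = math.comb(n - v - 1, slot - 1)
            if rank < block:
                out.append(v)
                start = v + 1
                break
            rank -= block
        else:  # pragma: no cover - rank validated by caller
            raise ValueError("combination rank out of range")
    return tuple(out)


def _rank_combination(comb: tuple[int, ...], n: int) -> int:
    k = len(comb)
    rank = 0
    prev = -1
    for slot, v in enumerate(comb):
        for u in range(prev + 1, v):
            rank += math.comb(n - u - 1, k - slot - 1)
        prev = v
    return rank


def _group_assignments(
    d: DesignInfo, plan: PermutationPlan, rng: np.random.Generator
) -> tuple[list[np.ndarray], PermutationPlan]:
    """Row-index sets assigned to the first group level, one per replicate."""
    mask_a, _ = d.two_group_masks()
    n = d.n
    n1 = int(mask_a.sum())
    n2 = n - n1
    equal = n1 == n2
    distinct = count_distinct_assignments("group_label", n1=n1, n2=n2)
    plan = _check_plan(plan, distinct)

    # canonical representation: the size-n1 subset; when n1 == n2 the
    # representative is the half containing row 0 (label swap is the same test)
    def canonical(rows: tuple[int, ...]) -> tuple[int, ...]:
        if equal and 0 not in rows:
            return tuple(sorted(set(range(n)) - set(rows)))
        return rows

    identity = canonical(tuple(np.where(mask_a)[0]))

    if plan.exhaustive:
        from itertools import combinations

        pool = range(1, n) if equal else range(n)
        size = n1 - 1 if equal else n1
        combs = [
            (0,) + c if equal else c for c in combinations(pool, size)
        ]
        return [np.array(c) for c in combs], plan

    # sampled: draw uniformly from the distinct set minus the identity
    if distinct <= 10 * plan.B:  # without replacement via combination unranking
        if equal:
            total, pool_n, pool_k = math.comb(n - 1, n1 - 1), n - 1, n1 - 1
            id_rank = _rank_combination(tuple(v - 1 for v in identity[1:]), pool_n)
        else:
            total, pool_n, pool_k = math.comb(n, n1), n, n1
            id_rank = _rank_combination(identity, pool_n)
        n_draw = min(plan.B, total - 1)
        ranks = rng.choice(total - 1, size=n_draw, replace=False)
        ranks = np.where(ranks >= id_rank, ranks + 1, ranks)
        combs = []
        for r in ranks:
            c = _unrank_combination(int(r), pool_n, pool_k)
            combs.append((0,) + tuple(v + 1 for v in c) if equal else c)
        return [np.array(c) for c in combs], plan

    # with replacement: huge assignment spaces
    out = []
    while len(out) < plan.B:
        rows = canonical(tuple(sorted(rng.choice(n, size=n1, replace=False))))
        if rows != identity:
            out.append(np.array(rows))
    return out, plan


def _sign_assignments(
    d: DesignInfo, plan: PermutationPlan, rng: np.random.Generator
) -> tuple[list[np.ndarray], PermutationPlan, list[tuple[int, int]]]:
    """Sign vectors over pairs (first pair fixed +1), one per replicate."""
    rows = d.pair_rows()
    k = len(rows)
    distinct = count_distinct_assignments("sign_flip", k=k)
    plan = _check_plan(plan, distinct)

    def signs_from_bits(code: int) -> np.ndarray:
        s = np.ones(k, dtype=int)
        for j in range(1, k):
            if (code >> (j - 1)) & 1:
                s[j] = -1
        return s

    if plan.exhaustive:
        codes = range(distinct)
    elif distinct <= 10 * plan.B:
        n_draw = min(plan.B, distinct - 1)
        codes = rng.choice(distinct - 1, size=n_draw, replace=False) + 1  # skip identity 0
    else:
        codes = []
        while len(codes) < plan.B:
            c = int(rng.integers(1, distinct))
            codes.append(c)
    return [signs_from_bits(int(c)) for c in codes], plan, rows


def _check_plan(plan: PermutationPlan, distinct: int) -> PermutationPlan:
    if distinct < plan.min_distinct_required:
        raise ValueError(
            f"only {distinct} distinct assignments are available, but estimating "
            f"the {plan.percentile:.0%} percentile requires at least "
            f"{plan.min_distinct_required}; use a larger sample or a lower percentile"
        )
    exhaustive = plan.exhaustive
    if exhaustive is None:
        exhaustive = distinct <= plan.B
    if exhaustive:
        B = distinct
    else:
        B = plan.B
    return replace(plan, exhaustive=exhaustive, B=B, distinct_available=distinct)


def generate_null_histograms(
    X: FeatureMatrix,
    d: DesignInfo,
    test: TestFunction,
    plan: PermutationPlan,
    cfg: BinningConfig | None = None,
) -> PermutationNullSummary:
    """Run the test on permuted data and summarize the null histograms.

    For each replicate the rows of X are re-assigned intact (group relabel
    or pair swap), the test is applied, its p-values are binned, and the
    first-bin and maximum bin counts are recorded.  The returned thresholds
    are the requested empirical percentile of those counts.  Results are
    bit-reproducible given ``plan.seed``; exhaustive enumeration consumes no
    randomness at all.
    """
    cfg = cfg or BinningConfig()
    rng = np.random.default_rng(plan.seed)

    if plan.scheme == "group_label":
        assignments, plan = _group_assignments(d, plan, rng)
        levels = d.levels

        def run(assign: np.ndarray):
            labels = np.full(d.n, levels[1], dtype=object)
            labels[assign] = levels[0]
            return test(X, DesignInfo(group=tuple(labels)))

    else:  # sign_flip
        assignments, plan, pair_rows = _sign_assignments(d, plan, rng)

        def run(signs: np.ndarray):
            perm = np.arange(X.n)
            for (i1, i2), s in zip(pair_rows, signs):
                if s < 0:
                    perm[i1], perm[i2] = perm[i2], perm[i1]
            Xp = FeatureMatrix(X.values[perm], X.sample_ids, X.feature_ids)
            return test(Xp, d)

    first_bin = np.empty(len(assignments), dtype=int)
    max_bin = np.empty(len(assignments), dtype=int)
    for r, assign in enumerate(assignments):
        counts = bin_pvalues(run(assign), cfg)
        first_bin[r] = counts.first_bin
        max_bin[r] = counts.max_bin

    return PermutationNullSummary(
        first_bin_counts=first_bin,
        max_bin_counts=max_bin,
        hc_threshold_perm=_percentile(first_bin, plan.percentile),
        qc_threshold_perm=_percentile(max_bin, plan.percentile),
        percentile=plan.percentile,
        plan=plan,
    )
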