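"""Vectorized feature-wise tests over an n-samples-by-m-features matrix.

Each test maps a :class:`FeatureMatrix` and :class:`DesignInfo` to one
two-sided p-value per feature.  The same signature is the pluggable
``TestFunction`` contract the permutation engine accepts, so any
user-supplied per-feature test (an ANOVA contrast, a moderated statistic,
...) can be dropped in.

Degenerate zero-variance features yield documented limit p-values (1 when
the group means agree, 0 when they differ) rather than errors: simulators
at tiny n can and do generate constant features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .histogram import PValueVector

__all__ = [
    "FeatureMatrix",
    "DesignInfo",
    "TestFunction",
    "two_sample_t",
    "welch_t",
    "paired_t",
    "wilcoxon_rank_sum",
    "read_matrix_tsv",
    "read_design_tsv",
    "TEST_REGISTRY",
]

#: largest per-group size for which the exact rank-sum null is enumerated
_WILCOXON_EXACT_MAX_N = 12


@dataclass(frozen=True)
class FeatureMatrix:
    """n-by-m matrix of feature values; rows are experimental units."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"feature matrix must be 2-d, got shape {arr.shape}")
        n, m = arr.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples (rows), got {n}")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_ids[c]!r}; missing entries are not supported"
            )
        if len(self.sample_ids) != n or len(self.feature_ids) != m:
            raise ValueError("sample_ids / feature_ids lengths do not match the matrix")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "feature_ids", tuple(map(str, self.feature_ids)))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        sample_ids: Sequence[str] | None = None,
        feature_ids: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        n, m = values.shape
        if sample_ids is None:
            sample_ids = [f"s{i+1}" for i in range(n)]
        if feature_ids is None:
            feature_ids = [f"f{j+1}" for j in range(m)]
        return cls(values, tuple(sample_ids), tuple(feature_ids))


@dataclass(frozen=True)
class DesignInfo:
    """Per-sample group labels and, for paired designs, pair identifiers."""

    group: tuple[str, ...]
    pair_id: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", tuple(map(str, self.group)))
        if self.pair_id is not None:
            pid = tuple(map(str, self.pair_id))
            if len(pid) != len(self.group):
                raise ValueError("pair_id length must match group length")
            object.__setattr__(self, "pair_id", pid)

    @property
    def n(self) -> int:
        return len(self.group)

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.group)))

    def two_group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean row masks for the two groups (levels in sorted order)."""
        levels = self.levels
        if len(levels) != 2:
            raise ValueError(
                f"two-sample tests need exactly two group labels, got {levels}"
            )
        g = np.asarray(self.group)
        mask_a, mask_b = g == levels[0], g == levels[1]
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            raise ValueError(
                f"each group needs >= 2 samples, got "
                f"{levels[0]}: {int(mask_a.sum())}, {levels[1]}: {int(mask_b.sum())}"
            )
        return mask_a, mask_b

    def pair_rows(self) -> list[tuple[int, int]]:
        """(group-1 row, group-2 row) index pairs, one per pair_id."""
        if self.pair_id is None:
            raise ValueError("this design has no pair_id column")
        levels = self.levels
        if len(levels) != 2:
            raise ValueError(
                f"paired tests need exactly two group labels, got {levels}"
            )
        pairs: dict[str, dict[str, int]] = {}
        for i, (g, pid) in enumerate(zip(self.group, self.pair_id)):
            slot = pairs.setdefault(pid, {})
            if g in slot:
                raise ValueError(f"pair {pid!r} has two samples in group {g!r}")
            slot[g] = i
        out = []
        for pid in sorted(pairs):
            slot = pairs[pid]
            if set(slot) != set(levels):
                raise ValueError(
                    f"pair {pid!r} must have one sample in each group, got {sorted(slot)}"
                )
            out.append((slot[levels[0]], slot[levels[1]]))
        if len(out) < 2:
            raise ValueError(f"paired tests need >= 2 pairs, got {len(out)}")
        return out


#: contract: (FeatureMatrix, DesignInfo) -> PValueVector of length m
TestFunction = Callable[[FeatureMatrix, DesignInfo], PValueVector]


def _degenerate_two_sample(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Replace NaN p-values where both groups have zero variance."""
    var0 = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if var0.any():
        equal = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p = p.copy()
        p[var0 & equal] = 1.0
        p[var0 & ~equal] = 0.0
    return np.nan_to_num(p, nan=1.0)


def two_sample_t(
    X: FeatureMatrix, d: DesignInfo, variance: str = "pooled"
) -> PValueVector:
    """Two-sided two-sample t-test per feature.

    ``variance="pooled"`` is the classic Student t with n1+n2-2 degrees of
    freedom; ``"welch"`` uses the Welch-Satterthwaite approximation.
    """
    if variance not in ("pooled", "welch"):
        raise ValueError(f"variance must be 'pooled' or 'welch', got {variance!r}")
    mask_a, mask_b = d.two_group_masks()
    a, b = X.values[mask_a], X.values[mask_b]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant features trigger scipy's catastrophic-cancellation warning;
        # the documented degenerate rule below handles them
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=(variance == "pooled"))
    return PValueVector(_degenerate_two_sample(np.asarray(res.pvalue), a, b))


def welch_t(X: FeatureMatrix, d: DesignInfo) -> PValueVector:
    return two_sample_t(X, d, variance="welch")


def paired_t(X: FeatureMatrix, d: DesignInfo) -> PValueVector:
    """Two-sided one-sample t-test on within-pair differences, per feature."""
    rows = d.pair_rows()
    i1 = [r[0] for r in rows]
    i2 = [r[1] for r in rows]
    diffs = X.values[i2] - X.values[i1]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_1samp(diffs, 0.0, axis=0)
    p = np.asarray(res.pvalue)
    var0 = diffs.var(axis=0) == 0
    if var0.any():
        p = p.copy()
        zero_mean = np.isclose(diffs.mean(axis=0), 0.0)
        p[var0 & zero_mean] = 1.0
        p[var0 & ~zero_mean] = 0.0
    return PValueVector(np.nan_to_num(p, nan=1.0))


def wilcoxon_rank_sum(X: FeatureMatrix, d: DesignInfo) -> PValueVector:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test per feature.

    The exact null distribution is enumerated for group sizes <= 12 on
    features without ties; ties (midranks) and larger groups use the
    tie-corrected normal approximation with continuity correction.
    """
    mask_a, mask_b = d.two_group_masks()
    a, b = X.values[mask_a], X.values[mask_b]
    n1, n2 = a.shape[0], b.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        p_asymp = np.asarray(
            stats.mannwhitneyu(a, b, axis=0, method="asymptotic").pvalue
        )
    p = p_asymp
    if n1 <= _WILCOXON_EXACT_MAX_N and n2 <= _WILCOXON_EXACT_MAX_N:
        combined = np.sort(X.values, axis=0)
        no_ties = ~(np.diff(combined, axis=0) == 0).any(axis=0)
        if no_ties.any():
            p_exact = np.asarray(
                stats.mannwhitneyu(
                    a[:, no_ties], b[:, no_ties], axis=0, method="exact"
                ).pvalue
            )
            p = p_asymp.copy()
            p[no_ties] = p_exact
    # all-tied (constant) features have zero rank variance -> maximally central
    return PValueVector(np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0))


#: named tests exposed on the command line and in reports
TEST_REGISTRY: dict[str, TestFunction] = {
    "ttest": two_sample_t,
    "welch": welch_t,
    "paired": paired_t,
    "wilcoxon": wilcoxon_rank_sum,
}


def read_matrix_tsv(path: str | Path) -> FeatureMatrix:
    """Read a feature matrix TSV: first column sample_id, one column per feature."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a sample_id column plus feature columns")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return FeatureMatrix(values, tuple(sample_ids), tuple(df.columns[1:]))


def read_design_tsv(path: str | Path, sample_ids: Sequence[str]) -> DesignInfo:
    """Read a design TSV (sample_id, group[, pair_id]), reconciled by sample_id.

    Row order in the file is irrelevant; rows are matched to the feature
    matrix by sample_id and every matrix sample must appear exactly once.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: design table needs columns {sorted(required)}")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"{path}: design table is missing sample_ids {missing}")
    df = df.loc[list(sample_ids)]
    pair = tuple(df["pair_id"]) if "pair_id" in df.columns else None
    return DesignInfo(group=tuple(df["group"]), pair_id=pair)
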