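"""p-value vectors, histogram binning, and QQ-plot coordinates.

Under the global null hypothesis every p-value is Uniform(0, 1), so a
histogram of the m p-values with K = 1/b equal-width bins has expected
count m*b in each bin.  The binned representation built here is the input
to the higher-criticism and quality-control tests in :mod:`pvhist.thresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "PValueVector",
    "BinningConfig",
    "HistogramCounts",
    "bin_pvalues",
    "qq_coordinates",
]


@dataclass(frozen=True)
class PValueVector:
    """An immutable vector of m p-values, each validated to lie in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"p-values must be a 1-d vector, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("p-value vector must contain at least one value")
        bad = np.where(np.isnan(arr) | (arr < 0.0) | (arr > 1.0))[0]
        if bad.size:
            raise ValueError(
                f"p-value at index {bad[0]} is {arr[bad[0]]!r}, outside [0, 1]"
                + (f" ({bad.size} offending values in total)" if bad.size > 1 else "")
            )
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def m(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.m

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "PValueVector":
        return cls(np.fromiter(values, dtype=float))


def as_pvalues(p: "PValueVector | Iterable[float]") -> PValueVector:
    """Coerce an array-like of p-values into a validated PValueVector."""
    if isinstance(p, PValueVector):
        return p
    return PValueVector(np.asarray(p, dtype=float))


@dataclass(frozen=True)
class BinningConfig:
    """Equal-width binning of [0, 1] into K = 1/b bins.

    The bin width must tile the unit interval exactly: the Bonferroni
    correction behind the quality-control threshold assumes exactly K bins.
    Non-tiling widths are rejected rather than silently truncated.
    """

    b: float = 0.05
    K: int = field(init=False)

    _TILE_TOL = 1e-9

    def __post_init__(self) -> None:
        if not (0.0 < self.b <= 1.0):
            raise ValueError(f"bin width b must lie in (0, 1], got {self.b}")
        K = round(1.0 / self.b)
        if K < 1 or abs(K * self.b - 1.0) > self._TILE_TOL:
            raise ValueError(
                f"bin width {self.b} does not tile [0, 1] exactly "
                f"(K*b = {K * self.b}); choose b = 1/K for integer K"
            )
        object.__setattr__(self, "K", int(K))

    @property
    def edges(self) -> np.ndarray:
        """K+1 bin edges; bins are [edge_k, edge_{k+1}), the last closed at 1."""
        return np.linspace(0.0, 1.0, self.K + 1)


@dataclass(frozen=True)
class HistogramCounts:
    """Bin counts c_1..c_K of a p-value histogram; counts[0] is the first bin."""

    config: BinningConfig
    counts: np.ndarray
    m: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (self.config.K,):
            raise ValueError(
                f"expected {self.config.K} bin counts, got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("bin counts must be non-negative")
        if int(counts.sum()) != self.m:
            raise ValueError(
                f"bin counts sum to {int(counts.sum())} but m = {self.m}"
            )
        counts.flags.writeable = False
        object.__setattr__(self, "counts", counts)

    @property
    def first_bin(self) -> int:
        """X, the number of p-values in the bin closest to zero."""
        return int(self.counts[0])

    @property
    def max_bin(self) -> int:
        return int(self.counts.max())


def bin_pvalues(
    p: PValueVector | Iterable[float], cfg: BinningConfig | None = None
) -> HistogramCounts:
    """Bin p-values into K equal-width bins on [0, 1].

    Bins are left-closed, right-open, except the last bin which is closed
    at 1 so that p = 1.0 is counted.  A p-value exactly on an interior edge
    belongs to the higher bin.
    """
    pv = as_pvalues(p)
    cfg = cfg or BinningConfig()
    # digitize against the exact edge grid: index i means edges[i-1] <= p < edges[i]
    idx = np.digitize(pv.values, cfg.edges, right=False) - 1
    idx = np.clip(idx, 0, cfg.K - 1)  # p = 1.0 folds into the closed last bin
    counts = np.bincount(idx, minlength=cfg.K)
    return HistogramCounts(config=cfg, counts=counts, m=pv.m)


def qq_coordinates(
    p: PValueVector | Iterable[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform QQ-plot coordinates: (expected quantiles, observed quantiles).

    Observed quantiles are the sorted p-values; expected quantiles use the
    plotting positions (i - 0.5)/m.  Under the global null the points lie on
    the identity line.
    """
    pv = as_pvalues(p)
    observed = np.sort(pv.values)
    expected = (np.arange(1, pv.m + 1) - 0.5) / pv.m
    return expected, observed
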