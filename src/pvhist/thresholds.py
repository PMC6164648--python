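"""Analytic higher-criticism and quality-control thresholds.

Under the global null, the count X of p-values in a histogram bin of width
b is Binomial(m, b).  The higher-criticism (HC) test rejects the global
null when the first-bin count strictly exceeds the (1 - alpha) binomial
quantile; the quality-control (QC) test Bonferroni-corrects over all K
bins and flags any bin whose count strictly exceeds the (1 - alpha/K)
quantile — a signal that the test statistics have departed from their
theoretical null distribution somewhere in [0, 1].

Quantiles are computed from the exact binomial CDF, never a normal
approximation; the classical closed-form alternative (Tukey's
higher-criticism statistic) is provided in both common variance
conventions for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .histogram import BinningConfig, HistogramCounts

__all__ = [
    "HCDecision",
    "QCDecision",
    "binomial_quantile",
    "hc_threshold",
    "qc_threshold",
    "tukey_hc_statistic",
    "tukey_rejection_threshold",
    "hc_decide",
    "qc_decide",
]

#: one-sided 5% critical value of the standard normal, used by Tukey's rule
TUKEY_CRITICAL = 1.645


def binomial_quantile(q: float, m: int, p: float) -> int:
    """min{k : P(Bin(m, p) <= k) >= q}, from the exact binomial CDF."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level q must lie in (0, 1), got {q}")
    if m < 1:
        raise ValueError(f"trial count m must be >= 1, got {m}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"success probability must lie in (0, 1), got {p}")
    k = int(stats.binom.ppf(q, m, p))
    # guard the discrete inversion at the boundary of floating-point ties
    while k > 0 and stats.binom.cdf(k - 1, m, p) >= q:
        k -= 1
    while stats.binom.cdf(k, m, p) < q:
        k += 1
    return k


def hc_threshold(m: int, cfg: BinningConfig | None = None, alpha: float = 0.05) -> int:
    """Higher-criticism threshold F_{1-alpha}(m, b) for the first-bin count.

    The HC test rejects the global null when the first-bin count strictly
    exceeds this value.
    """
    cfg = cfg or BinningConfig()
    return binomial_quantile(1.0 - alpha, m, cfg.b)


def qc_threshold(m: int, cfg: BinningConfig | None = None, alpha: float = 0.05) -> int:
    """Bonferroni-corrected QC threshold F_{1-alpha/K}(m, b), scanned over all K bins."""
    cfg = cfg or BinningConfig()
    return binomial_quantile(1.0 - alpha / cfg.K, m, cfg.b)


def tukey_hc_statistic(
    x: int,
    m: int,
    alpha0: float = 0.05,
    variant: str = "null_variance",
) -> float:
    """Tukey's higher-criticism statistic, a normal approximation to the binomial.

    With f = x/m the statistic is sqrt(m) * (f - alpha0) / denom where the
    denominator is sqrt(alpha0*(1-alpha0)) for ``null_variance`` (the
    variance under the null) or sqrt(f*(1-f)) for ``plugin_variance`` (the
    observed-proportion plug-in).  Reject the global null at the 5% level
    when the statistic exceeds 1.645.
    """
    if not 0 <= x <= m:
        raise ValueError(f"first-bin count x must lie in [0, m], got x={x}, m={m}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    f = x / m
    if variant == "null_variance":
        denom = np.sqrt(alpha0 * (1.0 - alpha0))
    elif variant == "plugin_variance":
        if x == 0 or x == m:
            raise ValueError(
                "plugin_variance is undefined at x = 0 or x = m (zero variance)"
            )
        denom = np.sqrt(f * (1.0 - f))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(np.sqrt(m) * (f - alpha0) / denom)


def tukey_rejection_threshold(
    m: int,
    alpha0: float = 0.05,
    variant: str = "plugin_variance",
    critical: float = TUKEY_CRITICAL,
) -> int:
    """Smallest first-bin count whose Tukey statistic exceeds the critical value."""
    for x in range(1, m + 1):
        if variant == "plugin_variance" and x == m:
            break
        if tukey_hc_statistic(x, m, alpha0, variant) > critical:
            return x
    raise ValueError(f"no count in 1..{m} exceeds the critical value {critical}")


@dataclass(frozen=True)
class HCDecision:
    """Outcome of the higher-criticism test on the first histogram bin."""

    x: int
    threshold: int
    reject: bool
    tukey_null_variance: float
    tukey_plugin_variance: float | None
    critical_value: float = TUKEY_CRITICAL
    alpha: float = 0.05


@dataclass(frozen=True)
class QCDecision:
    """Outcome of the Bonferroni-corrected bin scan.

    ``flagged_bins`` holds 0-based bin indices whose count strictly exceeds
    the threshold; ``reject`` is True iff any bin is flagged.  An excess in
    the first bin is expected under genuine signal, so callers diagnosing
    experiment quality should look at :attr:`interior_flagged`.
    """

    threshold: int
    flagged_bins: tuple[int, ...]
    reject: bool
    alpha: float = 0.05
    per_bin_level: float = 0.0025

    @property
    def interior_flagged(self) -> tuple[int, ...]:
        """Flagged bins excluding the first (signal-expected) bin."""
        return tuple(k for k in self.flagged_bins if k != 0)


def hc_decide(counts: HistogramCounts, alpha: float = 0.05) -> HCDecision:
    """Higher criticism: is there a significant excess of low p-values?

    Rejection uses a strict inequality — the first-bin count must *exceed*
    the binomial quantile; a count exactly at the threshold does not reject.
    """
    x = counts.first_bin
    m = counts.m
    thr = hc_threshold(m, counts.config, alpha)
    plugin = (
        tukey_hc_statistic(x, m, counts.config.b, "plugin_variance")
        if 0 < x < m
        else None
    )
    return HCDecision(
        x=x,
        threshold=thr,
        reject=x > thr,
        tukey_null_variance=tukey_hc_statistic(x, m, counts.config.b, "null_variance"),
        tukey_plugin_variance=plugin,
        alpha=alpha,
    )


def qc_decide(counts: HistogramCounts, alpha: float = 0.05) -> QCDecision:
    """Quality control: has any bin count exceeded its Bonferroni-corrected bound?"""
    thr = qc_threshold(counts.m, counts.config, alpha)
    flagged = tuple(int(k) for k in np.where(counts.counts > thr)[0])
    return QCDecision(
        threshold=thr,
        flagged_bins=flagged,
        reject=bool(flagged),
        alpha=alpha,
        per_bin_level=alpha / counts.config.K,
    )
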