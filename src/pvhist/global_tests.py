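"""Global procedures over the full p-value vector: BH FDR control and the
Kolmogorov-Smirnov uniformity test.

BH answers the per-hypothesis question (which features can be rejected at a
target false discovery rate); KS is the bin-free companion to the binned QC
scan, testing the whole empirical distribution against Uniform(0, 1).  KS is
reported alongside, never instead of, the binned QC decision — the binned
test is what gives the histogram its visual threshold line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .histogram import PValueVector, as_pvalues

__all__ = ["BHResult", "KSResult", "bh_reject", "ks_uniform"]

#: below this sample size the exact KS null distribution is used
_KS_EXACT_MAX_M = 35


@dataclass(frozen=True)
class BHResult:
    """Benjamini-Hochberg step-up outcome at a target FDR level."""

    q_level: float
    n_rejected: int
    rejected_indices: np.ndarray
    adjusted_values: np.ndarray


@dataclass(frozen=True)
class KSResult:
    """One-sample KS test of the p-values against the uniform reference."""

    statistic: float
    p_value: float


def bh_reject(p: PValueVector | Iterable[float], q_level: float = 0.05) -> BHResult:
    """Benjamini-Hochberg step-up procedure controlling the FDR at ``q_level``.

    Sort the p-values ascending, find the largest i with p_(i) <= i*q/m and
    reject every hypothesis with a p-value at or below that cutoff.  Adjusted
    p-values are the standard step-up monotone adjustment capped at 1.
    """
    if not 0.0 < q_level < 1.0:
        raise ValueError(f"FDR level must lie in (0, 1), got {q_level}")
    pv = as_pvalues(p)
    reject, adjusted, _, _ = multipletests(
        pv.values, alpha=q_level, method="fdr_bh", is_sorted=False
    )
    idx = np.where(reject)[0]
    return BHResult(
        q_level=q_level,
        n_rejected=int(idx.size),
        rejected_indices=idx,
        adjusted_values=adjusted,
    )


def ks_uniform(p: PValueVector | Iterable[float]) -> KSResult:
    """One-sample Kolmogorov-Smirnov test against Uniform(0, 1).

    D is the exact sup-discrepancy between the ECDF and the uniform CDF,
    evaluated on both sides of every jump.  The exact null distribution of D
    is used for small m, the asymptotic one otherwise.
    """
    pv = as_pvalues(p)
    method = "exact" if pv.m < _KS_EXACT_MAX_M else "asymp"
    res = stats.kstest(pv.values, "uniform", method=method)
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue))
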