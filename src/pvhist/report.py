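"""End-to-end diagnosis of a p-value histogram.

A :func:`diagnose` run answers the two questions a p-value histogram poses
about an experiment as a whole:

* **Higher criticism** — is there a significant excess of low p-values,
  i.e. any evidence of a systematic response even if no individual
  hypothesis can be rejected?
* **Quality control** — has the histogram departed from uniformity
  somewhere it should not (an interior or right-side bump), indicating a
  problem with assumptions, design or processing?

The two binary answers are folded into a four-way classification:
``uniform``, ``enriched`` (HC only), ``irregular`` (QC only) or
``enriched_and_irregular``.  An excess confined to the first bin is
expected under genuine signal, so only flags outside the first bin drive
the "irregular" label; the full flag list is still reported.

When a feature matrix and design are available,
:func:`diagnose_with_permutation` additionally estimates
correlation-adjusted thresholds from the permutation null and bases the
classification on those instead of the independence-based bounds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import __version__ as _version
from .feature_tests import DesignInfo, FeatureMatrix, TestFunction
from .global_tests import BHResult, KSResult, bh_reject, ks_uniform
from .histogram import (
    BinningConfig,
    HistogramCounts,
    PValueVector,
    as_pvalues,
    bin_pvalues,
    qq_coordinates,
)
from .permutation import (
    PermutationNullSummary,
    PermutationPlan,
    generate_null_histograms,
)
from .thresholds import HCDecision, QCDecision, hc_decide, qc_decide

__all__ = [
    "DiagnosticReport",
    "diagnose",
    "diagnose_with_permutation",
    "render_annotated_histogram",
    "report_to_dict",
    "report_from_dict",
]

SCHEMA_VERSION = 1

CLASSIFICATIONS = ("uniform", "enriched", "irregular", "enriched_and_irregular")

#: pipeline-friendly exit codes keyed by classification
EXIT_CODES = {
    "uniform": 0,
    "enriched": 10,
    "irregular": 20,
    "enriched_and_irregular": 30,
}


@dataclass(frozen=True)
class DiagnosticReport:
    """Everything a diagnosis computed, ready for JSON serialization."""

    m: int
    config: BinningConfig
    counts: HistogramCounts
    hc: HCDecision
    qc: QCDecision
    ks: KSResult
    classification: str
    bh: BHResult | None = None
    permutation: PermutationNullSummary | None = None
    provenance: dict = field(default_factory=dict)
    pvalues: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def exit_code(self) -> int:
        return EXIT_CODES[self.classification]


def _classify(enriched: bool, irregular: bool) -> str:
    if enriched and irregular:
        return "enriched_and_irregular"
    if enriched:
        return "enriched"
    if irregular:
        return "irregular"
    return "uniform"


def _provenance(extra: dict | None, seed=None, input_path=None) -> dict:
    prov = {"version": _version, "schema_version": SCHEMA_VERSION}
    if seed is not None:
        prov["seed"] = seed
    if input_path is not None:
        input_path = Path(input_path)
        prov["input"] = str(input_path)
        prov["input_sha256"] = hashlib.sha256(input_path.read_bytes()).hexdigest()
    if extra:
        prov.update(extra)
    return prov


def diagnose(
    p: PValueVector | Iterable[float],
    cfg: BinningConfig | None = None,
    alpha: float = 0.05,
    fdr_level: float | None = None,
    input_path: str | Path | None = None,
    provenance: dict | None = None,
) -> DiagnosticReport:
    """Run the full analytic diagnosis on a vector of p-values."""
    pv = as_pvalues(p)
    cfg = cfg or BinningConfig()
    counts = bin_pvalues(pv, cfg)
    hc = hc_decide(counts, alpha)
    qc = qc_decide(counts, alpha)
    ks = ks_uniform(pv)
    bh = bh_reject(pv, fdr_level) if fdr_level is not None else None
    classification = _classify(hc.reject, bool(qc.interior_flagged))
    return DiagnosticReport(
        m=pv.m,
        config=cfg,
        counts=counts,
        hc=hc,
        qc=qc,
        ks=ks,
        bh=bh,
        classification=classification,
        provenance=_provenance(provenance, input_path=input_path),
        pvalues=pv.values,
    )


def diagnose_with_permutation(
    X: FeatureMatrix,
    d: DesignInfo,
    test: TestFunction,
    plan: PermutationPlan,
    cfg: BinningConfig | None = None,
    alpha: float = 0.05,
    fdr_level: float | None = None,
    provenance: dict | None = None,
) -> DiagnosticReport:
    """Diagnose observed p-values with correlation-adjusted thresholds.

    The observed p-values come from ``test(X, d)``; the report contains both
    the analytic (independence) thresholds and the permutation thresholds,
    and the classification uses the permutation ones.
    """
    cfg = cfg or BinningConfig()
    pv = test(X, d)
    counts = bin_pvalues(pv, cfg)
    hc = hc_decide(counts, alpha)
    qc = qc_decide(counts, alpha)
    ks = ks_uniform(pv)
    bh = bh_reject(pv, fdr_level) if fdr_level is not None else None
    summary = generate_null_histograms(X, d, test, plan, cfg)

    enriched = counts.first_bin > summary.hc_threshold_perm
    interior = [
        int(k)
        for k in np.where(counts.counts > summary.qc_threshold_perm)[0]
        if k != 0
    ]
    classification = _classify(enriched, bool(interior))
    return DiagnosticReport(
        m=pv.m,
        config=cfg,
        counts=counts,
        hc=hc,
        qc=qc,
        ks=ks,
        bh=bh,
        permutation=summary,
        classification=classification,
        provenance=_provenance(provenance, seed=plan.seed),
        pvalues=pv.values,
    )


def render_annotated_histogram(
    report: DiagnosticReport, statistics: np.ndarray | None = None
) -> dict:
    """Plot-ready data for a threshold-annotated p-value histogram.

    Returns bin edges, counts, one horizontal line per available threshold
    (HC, QC, and the permutation pair when present), QQ coordinates, and —
    if raw test statistics are supplied — a test-statistic histogram.
    """
    lines = [
        {"label": "HC threshold (independence)", "value": float(report.hc.threshold)},
        {"label": "QC threshold (independence)", "value": float(report.qc.threshold)},
    ]
    if report.permutation is not None:
        # the correlation-adjusted line drawn on the histogram is the
        # permutation QC bound; the permutation HC bound stays in the JSON
        lines.append(
            {
                "label": f"Permutation ({report.permutation.percentile:.0%} of max bin counts)",
                "value": float(report.permutation.qc_threshold_perm),
            }
        )
    out = {
        "bin_edges": report.config.edges.tolist(),
        "counts": report.counts.counts.tolist(),
        "threshold_lines": lines,
        "classification": report.classification,
    }
    if report.pvalues is not None:
        expected, observed = qq_coordinates(report.pvalues)
        out["qq"] = {"expected": expected.tolist(), "observed": observed.tolist()}
    if statistics is not None:
        stat_counts, stat_edges = np.histogram(np.asarray(statistics), bins=30)
        out["statistic_histogram"] = {
            "counts": stat_counts.tolist(),
            "edges": stat_edges.tolist(),
        }
    return out


def report_to_dict(report: DiagnosticReport) -> dict:
    """JSON-serializable form of a report (replicate-level counts under 'audit')."""
    d: dict = {
        "schema_version": SCHEMA_VERSION,
        "m": report.m,
        "binning": {"b": report.config.b, "K": report.config.K},
        "counts": report.counts.counts.tolist(),
        "hc": {
            "x": report.hc.x,
            "threshold": report.hc.threshold,
            "reject": report.hc.reject,
            "tukey_null_variance": report.hc.tukey_null_variance,
            "tukey_plugin_variance": report.hc.tukey_plugin_variance,
            "critical_value": report.hc.critical_value,
            "alpha": report.hc.alpha,
        },
        "qc": {
            "threshold": report.qc.threshold,
            "flagged_bins": list(report.qc.flagged_bins),
            "interior_flagged": list(report.qc.interior_flagged),
            "reject": report.qc.reject,
            "alpha": report.qc.alpha,
            "per_bin_level": report.qc.per_bin_level,
        },
        "ks": {"statistic": report.ks.statistic, "p_value": report.ks.p_value},
        "classification": report.classification,
        "provenance": dict(report.provenance),
    }
    if report.bh is not None:
        d["bh"] = {
            "q_level": report.bh.q_level,
            "n_rejected": report.bh.n_rejected,
            "rejected_indices": report.bh.rejected_indices.tolist(),
        }
    if report.permutation is not None:
        s = report.permutation
        d["permutation"] = {
            "scheme": s.plan.scheme,
            "B": s.B,
            "seed": s.plan.seed,
            "exhaustive": s.plan.exhaustive,
            "distinct_available": s.plan.distinct_available,
            "percentile": s.percentile,
            "hc_threshold_perm": s.hc_threshold_perm,
            "qc_threshold_perm": s.qc_threshold_perm,
            "audit": {
                "first_bin_counts": s.first_bin_counts.tolist(),
                "max_bin_counts": s.max_bin_counts.tolist(),
            },
        }
    return d


def report_from_dict(d: dict) -> DiagnosticReport:
    """Rebuild a report from its serialized form (inverse of report_to_dict)."""
    cfg = BinningConfig(b=d["binning"]["b"])
    counts = HistogramCounts(config=cfg, counts=np.asarray(d["counts"]), m=d["m"])
    hc = HCDecision(
        x=d["hc"]["x"],
        threshold=d["hc"]["threshold"],
        reject=d["hc"]["reject"],
        tukey_null_variance=d["hc"]["tukey_null_variance"],
        tukey_plugin_variance=d["hc"]["tukey_plugin_variance"],
        critical_value=d["hc"]["critical_value"],
        alpha=d["hc"]["alpha"],
    )
    qc = QCDecision(
        threshold=d["qc"]["threshold"],
        flagged_bins=tuple(d["qc"]["flagged_bins"]),
        reject=d["qc"]["reject"],
        alpha=d["qc"]["alpha"],
        per_bin_level=d["qc"]["per_bin_level"],
    )
    ks = KSResult(statistic=d["ks"]["statistic"], p_value=d["ks"]["p_value"])
    bh = None
    if "bh" in d:
        idx = np.asarray(d["bh"]["rejected_indices"], dtype=int)
        bh = BHResult(
            q_level=d["bh"]["q_level"],
            n_rejected=d["bh"]["n_rejected"],
            rejected_indices=idx,
            adjusted_values=np.array([]),
        )
    permutation = None
    if "permutation" in d:
        s = d["permutation"]
        plan = PermutationPlan(
            scheme=s["scheme"],
            B=s["B"],
            seed=s["seed"],
            percentile=s["percentile"],
            exhaustive=s["exhaustive"],
            distinct_available=s["distinct_available"],
        )
        permutation = PermutationNullSummary(
            first_bin_counts=np.asarray(s["audit"]["first_bin_counts"], dtype=int),
            max_bin_counts=np.asarray(s["audit"]["max_bin_counts"], dtype=int),
            hc_threshold_perm=s["hc_threshold_perm"],
            qc_threshold_perm=s["qc_threshold_perm"],
            percentile=s["percentile"],
            plan=plan,
        )
    return DiagnosticReport(
        m=d["m"],
        config=cfg,
        counts=counts,
        hc=hc,
        qc=qc,
        ks=ks,
        bh=bh,
        permutation=permutation,
        classification=d["classification"],
        provenance=dict(d.get("provenance", {})),
    )


def write_report_json(report: DiagnosticReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2) + "\n")
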