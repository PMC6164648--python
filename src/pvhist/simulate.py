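"""Seeded generators for the failure-mode scenarios the diagnostics target.

Each scenario emulates a statistical signature seen in real high-throughput
experiments rather than any particular dataset:

* ``uniform_null`` — every null hypothesis true; p-values are i.i.d. uniform.
* ``low_power`` — a two-group normal-means experiment in which 20% of
  features carry a real (but often small) mean shift; at small n the BH
  procedure rejects nothing while the higher-criticism test still detects
  that non-null features exist.
* ``misspecified`` — all-null exponential data analyzed with a t-test at
  tiny n: the normality assumption fails and the p-value histogram is
  visibly non-uniform even though nothing is differentially expressed.
* ``correlated`` — all-null normal data with equicorrelated blocks of
  features sharing a per-sample latent factor; correlated "bundles" of
  features land together and produce bumps anywhere in the histogram,
  which the independence-based QC bound mistakes for a quality problem.

All generators are bit-reproducible: a single seed is split into
independent streams (feature placement / effect sizes vs. noise) through
numpy's SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .feature_tests import DesignInfo, FeatureMatrix

__all__ = [
    "ScenarioSpec",
    "ScenarioOutput",
    "simulate_uniform_null",
    "simulate_low_power",
    "simulate_misspecified",
    "simulate_correlated",
    "simulate_scenario",
    "write_scenario_tsvs",
]

ScenarioName = Literal["uniform_null", "low_power", "misspecified", "correlated"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic scenario (defaults are the study conditions)."""

    scenario: ScenarioName
    m: int = 10_000
    n: int = 4
    pi0: float = 0.8
    effect_low: float = -2.0
    effect_high: float = 2.0
    rate: float = 1.0
    rho: float = 0.75
    block_size: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.scenario != "uniform_null" and self.n < 2:
            raise ValueError(f"per-group sample size n must be >= 2, got {self.n}")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {self.block_size}")
        if self.rate <= 0:
            raise ValueError(f"exponential rate must be > 0, got {self.rate}")


@dataclass(frozen=True)
class ScenarioOutput:
    """Simulated data plus ground truth for power/recovery checks."""

    X: FeatureMatrix
    d: DesignInfo
    truth: pd.DataFrame  # columns: feature_id, is_null, effect
    spec: ScenarioSpec = field(repr=False, default=None)


def _streams(seed: int | None, n_streams: int) -> list[np.random.Generator]:
    """Independent child generators derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_streams)]


def _two_group_design(n: int) -> DesignInfo:
    return DesignInfo(group=tuple(["A"] * n + ["B"] * n))


def _feature_ids(m: int) -> tuple[str, ...]:
    width = len(str(m))
    return tuple(f"f{j + 1:0{width}d}" for j in range(m))


def simulate_uniform_null(m: int = 10_000, seed: int | None = None) -> np.ndarray:
    """m i.i.d. Uniform(0, 1) p-values — the idealized all-null histogram."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    (rng,) = _streams(seed, 1)
    return rng.uniform(0.0, 1.0, size=m)


def simulate_low_power(spec: ScenarioSpec) -> ScenarioOutput:
    """Two-group normal-means experiment with a fixed fraction of null features.

    Null features are N(0, 1) in both groups; for the remaining features the
    second group's mean is shifted by an effect drawn once per feature from
    Uniform(effect_low, effect_high).  Exactly round(pi0 * m) features are
    null, placed at random.
    """
    rng_truth, rng_noise = _streams(spec.seed, 2)
    m, n = spec.m, spec.n
    n_null = int(round(spec.pi0 * m))
    is_null = np.zeros(m, dtype=bool)
    is_null[rng_truth.permutation(m)[:n_null]] = True
    effect = np.zeros(m)
    effect[~is_null] = rng_truth.uniform(
        spec.effect_low, spec.effect_high, size=m - n_null
    )
    values = rng_noise.standard_normal((2 * n, m))
    values[n:] += effect  # group B rows get the per-feature mean shift
    fid = _feature_ids(m)
    truth = pd.DataFrame({"feature_id": fid, "is_null": is_null, "effect": effect})
    return ScenarioOutput(
        X=FeatureMatrix.from_arrays(values, feature_ids=fid),
        d=_two_group_design(n),
        truth=truth,
        spec=spec,
    )


def simulate_misspecified(spec: ScenarioSpec) -> ScenarioOutput:
    """All-null exponential data: every feature i.i.d. Exponential(rate) in
    both groups.  A t-test's normality assumption is badly wrong here at
    small n, which distorts the p-value histogram despite the global null
    holding exactly."""
    (rng,) = _streams(spec.seed, 1)
    m, n = spec.m, spec.n
    values = rng.exponential(scale=1.0 / spec.rate, size=(2 * n, m))
    fid = _feature_ids(m)
    truth = pd.DataFrame(
        {"feature_id": fid, "is_null": np.ones(m, dtype=bool), "effect": np.zeros(m)}
    )
    return ScenarioOutput(
        X=FeatureMatrix.from_arrays(values, feature_ids=fid),
        d=_two_group_design(n),
        truth=truth,
        spec=spec,
    )


def simulate_correlated(spec: ScenarioSpec) -> ScenarioOutput:
    """All-null equicorrelated blocks sharing a per-sample latent factor.

    Features are partitioned into consecutive blocks of ``block_size``; within
    a block each sample's values are sqrt(rho)*factor + sqrt(1-rho)*noise with
    a shared standard-normal factor per (sample, block), giving pairwise
    correlation rho within blocks and 0 across blocks.  Marginally every
    feature is still N(0, 1) in both groups, so the global null holds.
    """
    rng_factor, rng_noise = _streams(spec.seed, 2)
    m, n = spec.m, spec.n
    n_rows = 2 * n
    n_blocks = -(-m // spec.block_size)  # ceil
    block_of = np.repeat(np.arange(n_blocks), spec.block_size)[:m]
    factors = rng_factor.standard_normal((n_rows, n_blocks))
    noise = rng_noise.standard_normal((n_rows, m))
    values = np.sqrt(spec.rho) * factors[:, block_of] + np.sqrt(1 - spec.rho) * noise
    fid = _feature_ids(m)
    truth = pd.DataFrame(
        {"feature_id": fid, "is_null": np.ones(m, dtype=bool), "effect": np.zeros(m)}
    )
    return ScenarioOutput(
        X=FeatureMatrix.from_arrays(values, feature_ids=fid),
        d=_two_group_design(n),
        truth=truth,
        spec=spec,
    )


_SCENARIO_DEFAULTS: dict[str, dict] = {
    # the study conditions each scenario reproduces by default
    "uniform_null": {"m": 10_000},
    "low_power": {"m": 10_000, "n": 4, "pi0": 0.8, "effect_low": -2.0, "effect_high": 2.0},
    "misspecified": {"m": 10_000, "n": 3, "rate": 1.0, "pi0": 1.0},
    "correlated": {"m": 10_000, "n": 10, "rho": 0.75, "block_size": 500, "pi0": 1.0},
}


def simulate_scenario(scenario: ScenarioName, seed: int | None = None, **overrides):
    """Dispatch a scenario by name with its default study conditions.

    ``uniform_null`` returns a p-value array; the other scenarios return a
    :class:`ScenarioOutput` with data, design and ground truth.
    """
    if scenario not in _SCENARIO_DEFAULTS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIO_DEFAULTS)}"
        )
    params = {**_SCENARIO_DEFAULTS[scenario], **overrides}
    if scenario == "uniform_null":
        return simulate_uniform_null(m=params["m"], seed=seed)
    spec = ScenarioSpec(scenario=scenario, seed=seed, **params)
    fn = {
        "low_power": simulate_low_power,
        "misspecified": simulate_misspecified,
        "correlated": simulate_correlated,
    }[scenario]
    return fn(spec)


def write_scenario_tsvs(out: ScenarioOutput, directory: str | Path, prefix: str = "scenario") -> dict[str, Path]:
    """Write matrix/design/truth TSVs in the dialect the readers expect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / f"{prefix}_matrix.tsv",
        "design": directory / f"{prefix}_design.tsv",
        "truth": directory / f"{prefix}_truth.tsv",
    }
    mat = pd.DataFrame(out.X.values, columns=list(out.X.feature_ids))
    mat.insert(0, "sample_id", list(out.X.sample_ids))
    mat.to_csv(paths["matrix"], sep="\t", index=False)
    design = pd.DataFrame({"sample_id": list(out.X.sample_ids), "group": list(out.d.group)})
    if out.d.pair_id is not None:
        design["pair_id"] = list(out.d.pair_id)
    design.to_csv(paths["design"], sep="\t", index=False)
    out.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
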