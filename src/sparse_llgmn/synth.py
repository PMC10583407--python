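"""Synthetic feature tables: cohort-shaped and sparse-signal generators.

Two modes:

* **cohort** — draws a two-group table whose per-index means/SDs (continuous)
  or proportions (binary) follow a declared specification; a 41/14-participant,
  65-index spec mirroring the study cohort's published group summary statistics
  ships with the package.  Indices are drawn independently by default (the
  published summaries carry no covariances); an optional equicorrelation block
  adds a shared within-block factor.
* **sparse signal** — a ground-truth harness for selection methods: k
  informative columns with a known standardized mean difference between the
  classes, the rest pure noise.  The first informative index carries the full
  effect d and the remaining k-1 a common fraction (0.6) of it, so every
  planted signal is detectable at the default sample size while the
  "strongest" index is unambiguous for rank-based checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .feature_table import FeatureTable

SECONDARY_EFFECT_FRACTION = 0.6


@dataclass
class IndexSpec:
    """One index: continuous (per-group mean/sd) or binary (per-group
    proportion); optional block id for equicorrelated draws."""

    name: str
    kind: str  # "continuous" | "binary"
    group1: dict
    group2: dict
    block: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown index kind {self.kind!r}")
        for g in (self.group1, self.group2):
            if self.kind == "continuous":
                if g.get("sd", 0) < 0:
                    raise ValueError("sd must be >= 0")
            else:
                if not 0 <= g.get("proportion", -1) <= 1:
                    raise ValueError("proportion must lie in [0, 1]")


@dataclass
class CohortSpec:
    n_per_group: tuple[int, int]
    indices: list[IndexSpec]
    block_rho: dict[str, float] = field(default_factory=dict)
    clip: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [ix.name for ix in self.indices]
        if len(set(names)) != len(names):
            raise ValueError("index names must be unique")
        for rho in self.block_rho.values():
            if not 0 <= rho < 1:
                raise ValueError("equicorrelation rho must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            tuple(data["n_per_group"]),
            [IndexSpec(**entry) for entry in data["indices"]],
            data.get("block_rho", {}),
            {k: tuple(v) for k, v in data.get("clip", {}).items()},
        )


def bundled_cohort_spec() -> CohortSpec:
    """The packaged 41/14-participant, 65-index cohort specification."""
    ref = resources.files("sparse_llgmn").joinpath("data/cohort_spec.yaml")
    with resources.as_file(ref) as path:
        return CohortSpec.from_yaml(path)


def generate_cohort(
    spec: CohortSpec, seed: int, n_per_group: tuple[int, int] | None = None
) -> FeatureTable:
    """Draw a labelled table from a cohort spec.

    Continuous indices ~ Normal(group mean, group sd); binary ~ Bernoulli
    (group proportion).  Group 1 rows come first and carry label 1 (drivable).
    Indices sharing a block id are equicorrelated through a common standard
    normal factor: z = sqrt(rho) * z_block + sqrt(1 - rho) * eps.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = n_per_group or spec.n_per_group
    n = n1 + n2
    group2 = np.arange(n) >= n1
    p = len(spec.indices)
    values = np.empty((n, p))
    block_factors = {b: rng.standard_normal(n) for b in spec.block_rho}
    for j, ix in enumerate(spec.indices):
        if ix.kind == "continuous":
            z = rng.standard_normal(n)
            if ix.block in spec.block_rho:
                rho = spec.block_rho[ix.block]
                z = np.sqrt(rho) * block_factors[ix.block] + np.sqrt(1 - rho) * z
            mean = np.where(group2, ix.group2["mean"], ix.group1["mean"])
            sd = np.where(group2, ix.group2["sd"], ix.group1["sd"])
            col = mean + sd * z
            if ix.name in spec.clip:
                lo, hi = spec.clip[ix.name]
                col = np.clip(col, lo, hi)
        else:
            prob = np.where(group2, ix.group2["proportion"], ix.group1["proportion"])
            col = (rng.random(n) < prob).astype(float)
        values[:, j] = col
    labels = np.where(group2, 2, 1)
    return FeatureTable(values, labels, [ix.name for ix in spec.indices])


@dataclass
class SparseSignalSpec:
    """Ground-truth harness parameters for selection methods."""

    n_samples: int = 200
    n_indices: int = 30
    k_informative: int = 5
    effect_size: float = 1.5  # maximum standardized mean difference
    class_ratio: float = 0.5  # fraction of samples in the positive class
    noise_rho: float = 0.0  # equicorrelation among the noise columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.n_indices:
            raise ValueError("k must not exceed P")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not 0 < self.class_ratio < 1:
            raise ValueError("class ratio must lie in (0, 1)")

    def effects(self) -> np.ndarray:
        """Per-informative-index standardized mean differences: the lead index
        carries the full effect, the rest a common 0.6 fraction."""
        eff = np.full(self.k_informative, self.effect_size * SECONDARY_EFFECT_FRACTION)
        if self.k_informative:
            eff[0] = self.effect_size
        return eff


def generate_sparse_signal(spec: SparseSignalSpec) -> tuple[FeatureTable, set[str]]:
    """Generate a sparse-signal table and its informative-index ground truth.

    Informative column j (j = 0..k-1) separates the classes by effects()[j]
    standard deviations (class means at +-effect/2); the remaining P-k columns
    are standard normal noise, optionally equicorrelated.  Labels depend only
    on the fixed class split, never on realized noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_samples, spec.n_indices, spec.k_informative
    n_pos = int(round(n * spec.class_ratio))
    labels = np.where(np.arange(n) < n_pos, 1, 2)
    sign = np.where(labels == 1, 0.5, -0.5)

    values = rng.standard_normal((n, p))
    if spec.noise_rho > 0 and p > k:
        shared = rng.standard_normal(n)[:, None]
        values[:, k:] = (
            np.sqrt(spec.noise_rho) * shared
            + np.sqrt(1 - spec.noise_rho) * values[:, k:]
        )
    effects = spec.effects()
    values[:, :k] += sign[:, None] * effects[None, :]

    names = [f"signal_{j + 1}" for j in range(k)] + [
        f"noise_{j + 1}" for j in range(p - k)
    ]
    return FeatureTable(values, labels, names), set(names[:k])
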