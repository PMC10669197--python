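"""Tabular cohort simulator: subjects x 39 features with a known linear
age-generating process, for parameter-recovery tests of the modeling stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..cohort import FEATURE_COLUMNS, TABLE_COLUMNS

__all__ = ["FeatureDistribution", "CohortSpec", "simulate_tabular_cohort", "default_distributions"]


@dataclass(frozen=True)
class FeatureDistribution:
    """Normal sampling distribution with hard bounds (clipped)."""

    mean: float
    sd: float
    low: float = -np.inf
    high: float = np.inf


# Plausible per-feature-family defaults (mm, degrees/mm, dimensionless).
# These are fixtures chosen to be in an anatomically sensible range, not
# estimates of any real cohort.
_FAMILY_DEFAULTS: dict[str, FeatureDistribution] = {
    "lc": FeatureDistribution(35.0, 8.0, 5.0, 90.0),
    "l": FeatureDistribution(26.0, 6.0, 3.0, 80.0),
    "RL": FeatureDistribution(0.75, 0.10, 0.2, 1.0),
    "SOAM": FeatureDistribution(8.0, 3.0, 0.0, 30.0),
    "PAD": FeatureDistribution(12.0, 5.0, 0.0, 60.0),
    "TI": FeatureDistribution(1.05, 0.03, 1.0, 1.5),
    "diam_mean": FeatureDistribution(3.5, 0.6, 1.0, 7.0),
    "diam_min": FeatureDistribution(2.4, 0.5, 0.5, 6.0),
    "diam_max": FeatureDistribution(4.6, 0.7, 1.5, 9.0),
    "diam_std": FeatureDistribution(0.5, 0.2, 0.0, 2.0),
    "diam_p25": FeatureDistribution(3.1, 0.6, 0.8, 7.0),
    "diam_p50": FeatureDistribution(3.5, 0.6, 1.0, 7.0),
    "diam_p75": FeatureDistribution(3.9, 0.6, 1.2, 8.0),
}


def default_distributions() -> dict[str, FeatureDistribution]:
    """Independent default sampling distribution for each of the 39 features."""
    return {name: _FAMILY_DEFAULTS[name.split("_", 1)[1]] for name in FEATURE_COLUMNS}


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a tabular cohort.

    ``age = intercept + coefficients . features + N(0, noise_sd)``.
    """

    n_subjects: int
    coefficients: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 49.3
    noise_sd: float = 5.0
    distributions: Mapping[str, FeatureDistribution] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 8:
            raise ValueError(f"n_subjects must be >= 8 (4 folds of >= 2), got {self.n_subjects}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        unknown = [k for k in self.coefficients if k not in FEATURE_COLUMNS]
        if unknown:
            raise ValueError(f"coefficients reference unknown feature names: {sorted(unknown)}")
        if self.distributions is not None:
            unknown = [k for k in self.distributions if k not in FEATURE_COLUMNS]
            if unknown:
                raise ValueError(f"distributions reference unknown feature names: {sorted(unknown)}")


def simulate_tabular_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw an independent feature table and linear-plus-noise ages.

    Deterministic under ``spec.seed``; returns the canonical modeling table
    (subject_id, age, 39 features).
    """
    dists = default_distributions()
    if spec.distributions:
        dists.update(spec.distributions)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    data: dict[str, np.ndarray] = {}
    for name in FEATURE_COLUMNS:
        d = dists[name]
        data[name] = np.clip(rng.normal(d.mean, d.sd, size=n), d.low, d.high)
    age = np.full(n, float(spec.intercept))
    for name, coef in spec.coefficients.items():
        age = age + coef * data[name]
    if spec.noise_sd > 0:
        age = age + rng.normal(0.0, spec.noise_sd, size=n)
    width = len(str(n - 1))
    table = pd.DataFrame({"subject_id": [f"sim{idx:0{width}d}" for idx in range(n)], "age": age})
    for name in FEATURE_COLUMNS:
        table[name] = data[name]
    return table[list(TABLE_COLUMNS)]
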