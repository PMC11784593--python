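"""Shared fixtures and small-cohort helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mscolor.data_model import (
    LongitudinalDataset,
    StageData,
    apply_dataset_scalers,
    fit_dataset_scalers,
)
from mscolor.synthetic import SimConfig, simulate_study


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """Fast generator settings for unit tests (seconds, not minutes)."""
    base = dict(
        n_per_stage=[30, 30],
        d=8,
        c=2,
        m=2,
        n_causal=3,
        n_gwas=500,
        n_ref=200,
        seed=seed,
    )
    base.update(overrides)
    if "stage_slope_profile" not in base:
        base["stage_slope_profile"] = [1.0, 1.8, 0.7, 1.2][: len(base["n_per_stage"])]
    return SimConfig(**base)


def standardized(data: LongitudinalDataset) -> LongitudinalDataset:
    return apply_dataset_scalers(data, fit_dataset_scalers(data))


def toy_dataset(seed: int = 0, *, n: int = 12, d: int = 4, c: int = 2,
                stages: int = 2, visits: int = 3) -> LongitudinalDataset:
    """Hand-rolled dataset with exact control over shapes and ids."""
    rng = np.random.default_rng(seed)
    subj = [f"S{i:03d}" for i in range(n)]
    snps = [f"rs{j:04d}" for j in range(d)]
    qts = [f"QT{j + 1}" for j in range(c)]
    times = np.arange(visits) * 6.0
    stage_list = []
    for s in range(stages):
        geno = rng.standard_normal((n, d))
        z = rng.standard_normal((visits, n, c))
        stage_list.append(StageData(s + 1, list(subj), geno, z, times.copy(), qts, snps))
    return LongitudinalDataset(stages=stage_list)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    return simulate_study(small_config(seed=11))


@pytest.fixture(scope="session")
def small_study_std(small_study):
    return standardized(small_study.data)
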