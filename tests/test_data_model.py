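"""Unit tests for the core data containers and standardization."""

import numpy as np
import pandas as pd
import pytest

from mscolor.data_model import (
    LongitudinalDataset,
    StageData,
    apply_dataset_scalers,
    fit_dataset_scalers,
    residualize_covariates,
    standardize,
)
from conftest import toy_dataset


def test_standardize_zscores_columns():
    rng = np.random.default_rng(0)
    x = rng.normal(3.0, 2.5, size=(40, 5))
    std = standardize(x)
    assert np.allclose(std.values.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(std.values.std(axis=0, ddof=1), 1.0, atol=1e-12)
    assert np.allclose(std.inverse(), x)
    assert np.allclose(std.transform(x), std.values)


def test_standardize_constant_column_raises_or_drops():
    x = np.ones((10, 3))
    x[:, 0] = np.arange(10)
    with pytest.raises(ValueError, match="zero variance"):
        standardize(x)
    std = standardize(x, drop_constant=True)
    assert list(std.kept) == [0]
    assert std.values.shape == (10, 1)


def test_standardize_needs_two_rows():
    with pytest.raises(ValueError, match="2 rows"):
        standardize(np.ones((1, 2)))


def test_stage_data_shape_validation():
    with pytest.raises(ValueError, match="shape"):
        StageData(1, ["a", "b"], np.zeros((2, 3)), np.zeros((2, 3, 1)),
                  np.array([0.0, 6.0]), ["QT1"], ["s1", "s2", "s3"])
    with pytest.raises(ValueError, match="increasing"):
        StageData(1, ["a", "b"], np.zeros((2, 3)), np.zeros((2, 2, 1)),
                  np.array([6.0, 0.0]), ["QT1"], ["s1", "s2", "s3"])
    with pytest.raises(ValueError, match="non-finite"):
        StageData(1, ["a", "b"], np.full((2, 3), np.nan), np.zeros((2, 2, 1)),
                  np.array([0.0, 6.0]), ["QT1"], ["s1", "s2", "s3"])


def test_registry_is_sorted_union_and_rows_map_back():
    data = toy_dataset(0)
    st0 = data.stages[0]
    sub = st0.subset(st0.subject_ids[::2])
    extra = StageData(2, sub.subject_ids, sub.genotype, sub.qts, sub.times,
                      sub.qt_names, sub.snp_ids)
    ds = LongitudinalDataset(stages=[st0, extra])
    assert ds.registry == sorted(set(st0.subject_ids))
    rows = ds.registry_rows(extra)
    assert [ds.registry[i] for i in rows] == extra.subject_ids


def test_presence_table():
    data = toy_dataset(1)
    keep = data.stages[1].subject_ids[:5]
    ds = LongitudinalDataset(stages=[data.stages[0], data.stages[1].subset(keep)])
    pres = ds.presence()
    assert pres[1].all()
    assert pres[2].sum() == 5
    assert set(pres.index[pres[2]]) == set(keep)


def test_subset_preserves_row_order_and_covariates():
    data = toy_dataset(2)
    cov = pd.DataFrame({"age": np.arange(12.0)}, index=data.stages[0].subject_ids)
    ds = LongitudinalDataset(stages=data.stages, covariates=cov)
    keep = data.stages[0].subject_ids[3:8]
    sub = ds.subset(keep)
    assert sub.stages[0].subject_ids == keep  # stage order preserved
    assert np.allclose(sub.stages[0].genotype, data.stages[0].genotype[3:8])
    assert list(sub.covariates.index) == keep


def test_snp_ids_must_match_across_stages():
    data = toy_dataset(3)
    bad = StageData(2, data.stages[1].subject_ids, data.stages[1].genotype,
                    data.stages[1].qts, data.stages[1].times,
                    data.stages[1].qt_names, list(reversed(data.stages[1].snp_ids)))
    with pytest.raises(ValueError, match="snp_ids"):
        LongitudinalDataset(stages=[data.stages[0], bad])


def test_residualize_covariates_orthogonality():
    rng = np.random.default_rng(4)
    idx = [f"S{i}" for i in range(30)]
    cov = pd.DataFrame({"age": rng.normal(70, 5, 30), "edu": rng.normal(16, 2, 30)},
                       index=idx)
    qts = pd.DataFrame(rng.standard_normal((30, 3)), index=idx,
                       columns=["QT1", "QT2", "QT3"])
    resid = residualize_covariates(qts, cov, ["age", "edu"])
    for col in cov.columns:
        assert np.allclose(resid.to_numpy().T @ cov[col].to_numpy(), 0.0, atol=1e-8)
    assert np.allclose(resid.sum(axis=0), 0.0, atol=1e-8)


def test_residualize_covariates_errors():
    rng = np.random.default_rng(5)
    idx = [f"S{i}" for i in range(10)]
    qts = pd.DataFrame(rng.standard_normal((10, 2)), index=idx, columns=["a", "b"])
    cov = pd.DataFrame({"age": rng.normal(size=9)}, index=idx[:9])
    with pytest.raises(ValueError, match="missing"):
        residualize_covariates(qts, cov, ["age"])
    cov2 = pd.DataFrame({"age": np.ones(10)}, index=idx)
    with pytest.raises(ValueError, match="rank deficient"):
        residualize_covariates(qts, cov2, ["age"])


def test_dataset_scalers_train_only_transform():
    data = toy_dataset(6, n=20)
    scalers = fit_dataset_scalers(data)
    std = apply_dataset_scalers(data, scalers)
    pooled = np.concatenate([st.qts.reshape(-1, 2) for st in std.stages])
    assert np.allclose(pooled.mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(pooled.std(axis=0, ddof=1), 1.0, atol=1e-10)
    # applying train scalers to other data uses the train parameters
    other = toy_dataset(7, n=20)
    std_other = apply_dataset_scalers(other, scalers)
    expect = (other.stages[0].qts - scalers.qt_mean) / scalers.qt_scale
    assert np.allclose(std_other.stages[0].qts, expect)
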