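"""Unit tests for scoring, cross-validation, selection and statistics."""

import numpy as np
import pandas as pd
import pytest

from mscolor.evaluation import (
    CvReport,
    anova_snp_effect,
    fit_method,
    nested_cv,
    rmse,
    select_lambda_cv,
    selection_metrics,
    significance_band,
    stage_rmse,
    stage_slope_tests,
    trajectory_correlations,
)
from mscolor.solver import SolverConfig

from conftest import small_config, standardized
from mscolor.synthetic import simulate_study


@pytest.fixture(scope="module")
def study():
    return simulate_study(small_config(21, n_per_stage=[40, 40]))


@pytest.fixture(scope="module")
def data(study):
    return standardized(study.data)


@pytest.fixture(scope="module")
def fits(study, data):
    cfg = SolverConfig(max_iter=60)
    return {
        "mscolor": fit_method(data, study.harmonized, "mscolor", 1.0, cfg),
        "msmml": fit_method(data, None, "msmml", 1.0, cfg),
        "smml": fit_method(data, None, "smml", 1.0, cfg),
        "smtr": fit_method(data, None, "smtr", 1.0, cfg),
    }


def test_rmse_definition():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([1.0, 2.0, 5.0])
    assert rmse(a, b) == pytest.approx(np.sqrt(4.0 / 3.0))
    with pytest.raises(ValueError):
        rmse(a, b[:2])


def test_fit_method_dispatch_and_validation(study, data, fits):
    assert fits["mscolor"].method == "mscolor"
    assert fits["msmml"].method == "msmml"
    assert fits["smml"].method == "smml"
    assert fits["smtr"].method == "smtr"
    with pytest.raises(ValueError, match="unknown method"):
        fit_method(data, None, "bogus", 1.0)
    with pytest.raises(ValueError, match="summary"):
        fit_method(data, None, "mscolor", 1.0)
    # tuple lam sets the two penalties separately
    fit = fit_method(data, None, "msmml", (0.5, 2.0), SolverConfig(max_iter=5))
    assert float(fit.config.lambda_p) == 0.5
    assert float(fit.config.lambda_q) == 2.0


def test_stage_rmse_train_is_mean_per_trajectory(data, fits):
    vals = stage_rmse(fits["mscolor"], data, unseen=False)
    assert vals.shape == (data.n_stages,)
    assert (vals > 0).all()
    # unseen predictions use population aging and are no better on the train fit
    unseen = stage_rmse(fits["mscolor"], data, unseen=True)
    assert (unseen >= vals - 1e-9).all()


def test_stage_rmse_supports_all_methods(data, fits):
    for name, fit in fits.items():
        vals = stage_rmse(fit, data, unseen=True)
        assert np.isfinite(vals).all(), name


def test_select_lambda_cv_deterministic_and_tie_break(study):
    grid = [0.1, 1.0]
    lam1 = select_lambda_cv(study.data, None, "msmml", grid, k=3, seed=0,
                            base_config=SolverConfig(max_iter=40))
    lam2 = select_lambda_cv(study.data, None, "msmml", grid, k=3, seed=0,
                            base_config=SolverConfig(max_iter=40))
    assert lam1 == lam2
    assert select_lambda_cv(study.data, None, "msmml", [1.0], k=3, seed=0) == 1.0
    with pytest.raises(ValueError, match="nonempty"):
        select_lambda_cv(study.data, None, "msmml", [], k=3, seed=0)


def test_nested_cv_report_shapes(study):
    report = nested_cv(study.data, None, "msmml", grid=[0.1, 1.0],
                       k_outer=3, k_inner=2, seed=0,
                       base_config=SolverConfig(max_iter=40))
    assert isinstance(report, CvReport)
    assert report.fold_test_rmse.shape == (3, study.data.n_stages)
    assert len(report.selected) == 3
    summ = report.summary()
    assert list(summ["stage"]) == [1, 2, "average"]
    assert report.mean_test_rmse == pytest.approx(
        float(report.fold_test_rmse.mean(axis=1).mean()))
    # folds partition the registry
    from mscolor.evaluation import _fold_assignment
    folds = _fold_assignment(study.data.registry, 3, 0)
    assert sorted(np.concatenate(folds)) == list(range(len(study.data.registry)))


def test_selection_metrics_scores_and_auc(study, data, fits):
    report = selection_metrics(fits["mscolor"], study.truth, top_k=3)
    d = len(data.snp_ids)
    assert report.scores.shape == (d,)
    assert len(report.ranking) == d
    assert report.auc is not None and 0.0 <= report.auc <= 1.0
    assert report.precision_at_k is not None
    assert report.top() == report.ranking[:3]
    # block scores: intercept/slope per stage, u included in the row max
    assert f"stage1_intercept" in report.block_scores.columns
    w_and_u = np.abs(np.column_stack([fits["mscolor"].u[0][:, None],
                                      fits["mscolor"].W[0]])).max(axis=1)
    assert np.allclose(report.block_scores["stage1_intercept"], w_and_u)
    # perfect separability check on a synthetic score vector
    from mscolor.evaluation import SelectionReport  # noqa: F401  (public export)


def test_selection_metrics_degenerate_support(study, fits):
    truth_all = type("T", (), {"causal_support": np.ones(len(study.data.snp_ids), bool)})
    rep = selection_metrics(fits["msmml"], truth_all)
    assert rep.auc is None and rep.auc_undefined


def test_selection_metrics_averages_over_fold_fits(study, data, fits):
    single = selection_metrics(fits["msmml"], study.truth)
    double = selection_metrics([fits["msmml"], fits["msmml"]], study.truth)
    assert np.allclose(single.scores, double.scores)


def test_significance_band_thresholds():
    assert significance_band(0.2) == "ns"
    assert significance_band(0.05) == "*"
    assert significance_band(0.01) == "**"
    assert significance_band(1e-3) == "***"
    assert significance_band(1e-5) == "****"
    with pytest.raises(ValueError):
        significance_band(1.5)


def test_stage_slope_tests_pairs_and_grouping(data, fits):
    df = stage_slope_tests(fits["mscolor"], data)
    qts = len(data.qt_names) + 1  # per QT plus the average
    assert len(df) == qts * (data.n_stages * (data.n_stages - 1)) // 2
    assert set(df.columns) == {"comparison", "qt", "t", "p", "band"}
    grouping = pd.Series(
        [i % 2 for i in range(len(data.registry))], index=data.registry)
    df2 = stage_slope_tests(fits["mscolor"], data, grouping=grouping)
    assert (df2["comparison"].str.contains("group")).all()


def test_trajectory_correlations_and_self_correlation(data, fits):
    fit = fits["mscolor"]
    # build a covariate equal to the fitted QT-average slope of stage 1
    st = data.stages[0]
    g = fit.config.gamma
    _, b = fit.stage_aging(data, 0)
    slope = (g * (st.genotype @ fit.V[0]) + (1 - g) * b).mean(axis=1)
    cov = pd.DataFrame({"self_slope": slope}, index=st.subject_ids)
    df = trajectory_correlations(fit, data, ["self_slope"], covariates=cov)
    row = df[(df["stage"] == 1) & (df["summary"] == "slope")].iloc[0]
    assert row["r"] == pytest.approx(1.0, abs=1e-12)
    assert row["band"] == "****"
    with pytest.raises(KeyError, match="not found"):
        trajectory_correlations(fit, data, ["missing"], covariates=cov)
    from mscolor.data_model import LongitudinalDataset
    bare = LongitudinalDataset(stages=data.stages)
    with pytest.raises(ValueError, match="covariate"):
        trajectory_correlations(fit, bare, ["self_slope"], covariates=None)


def test_anova_snp_effect_detects_real_effect_and_validates():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, 500).astype(float)
    cov = pd.DataFrame({"age": rng.normal(70, 5, 500)})
    y = 0.8 * g + 0.02 * cov["age"].to_numpy() + rng.standard_normal(500)
    f, p = anova_snp_effect(g, y, cov)
    assert p < 1e-6 and f > 10
    with pytest.raises(ValueError, match="variation"):
        anova_snp_effect(np.ones(10), np.arange(10.0))
    with pytest.raises(ValueError, match="1-d"):
        anova_snp_effect(np.ones((5, 2)), np.ones((5, 2)))
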