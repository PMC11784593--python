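"""Model scoring, nested cross-validation, SNP selection and statistics.

Four groups of procedures:

* **fit quality** — per-trajectory RMSE and subject-level nested CV with
  train-only standardization;
* **SNP selection** — per-SNP weight scores from fitted coefficient blocks,
  with AUC / precision@k against a simulated causal support;
* **progression statistics** — two-sample t-tests between fitted stage slope
  distributions (with the conventional significance banding), Pearson
  correlations between per-subject trajectory summaries and cognitive scores,
  and a covariate-adjusted one-way ANOVA of a SNP's dosage effect on
  diagnosis;
* **replicate studies** — seeded support-recovery and method-ordering
  experiments over freshly simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .baselines import SmtrFit, fit_msmml, fit_smml, fit_smtr, pool_stages
from .data_model import LongitudinalDataset, apply_dataset_scalers, fit_dataset_scalers
from .gwas import HarmonizedSummary
from .solver import MscolorFit, SolverConfig, fit_mscolor, predict
from .synthetic import SimConfig, SimTruth, simulate_study

__all__ = [
    "rmse", "CvReport", "nested_cv", "SelectionReport", "selection_metrics",
    "significance_band", "stage_slope_tests", "trajectory_correlations",
    "anova_snp_effect", "fit_method", "stage_rmse", "select_lambda_cv",
    "support_recovery_replicate", "rmse_ordering_replicate",
]

METHODS = ("mscolor", "msmml", "smml", "smtr")


# ---------------------------------------------------------------------------
# RMSE and prediction plumbing
# ---------------------------------------------------------------------------

def rmse(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Root mean squared residual over the entries of one trajectory vector."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted must have the same shape")
    return float(np.sqrt(np.mean((observed - fitted) ** 2)))


def _default_offsets(data: LongitudinalDataset) -> list[float]:
    offsets, acc = [], 0.0
    for st in data.stages:
        offsets.append(acc)
        acc += float(st.times[-1] - st.times[0]) if st.n_visits > 1 else 1.0
    return offsets


def _pooled_schedule(data: LongitudinalDataset) -> list[tuple[int, int, float]]:
    """(stage index, visit index, global time) in the `pool_stages` slice order."""
    entries = []
    for s, (st, off) in enumerate(zip(data.stages, _default_offsets(data))):
        for k, t in enumerate(st.times):
            entries.append((s, k, off + float(t) - float(st.times[0])))
    order = np.argsort([e[2] for e in entries], kind="stable")
    return [entries[i] for i in order]


def fit_method(
    data: LongitudinalDataset,
    summary: HarmonizedSummary | None,
    method: str,
    lam: float | tuple[float, float],
    base_config: SolverConfig | None = None,
) -> MscolorFit | SmtrFit:
    """Fit one of the four methods with penalty weight(s) ``lam``."""
    lam_p, lam_q = (lam, lam) if np.isscalar(lam) else lam
    cfg = base_config or SolverConfig()
    if method == "mscolor":
        if summary is None:
            raise ValueError("mscolor requires harmonized summary statistics")
        return fit_mscolor(data, summary, replace(cfg, lambda_p=lam_p, lambda_q=lam_q))
    if method == "msmml":
        return fit_msmml(data, lam_p, lam_q, gamma=cfg.gamma, config=cfg)
    if method == "smml":
        return fit_smml(data, lam_p, lam_q, config=cfg)
    if method == "smtr":
        return fit_smtr(data, lam_p, max_iter=cfg.max_iter, tol=cfg.tol,
                        delta=cfg.smoothing_delta)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _predict_stage_visit(
    fit: MscolorFit | SmtrFit,
    data: LongitudinalDataset,
    s: int,
    k: int,
    *,
    unseen: bool,
) -> np.ndarray:
    """Predicted (n, c) QT matrix for stage ``s``, visit ``k`` of ``data``."""
    st = data.stages[s]
    t_local = float(st.times[k])
    if isinstance(fit, SmtrFit):
        sched = _pooled_schedule(data)
        j = next(i for i, (ss, kk, _) in enumerate(sched) if (ss, kk) == (s, k))
        return st.genotype @ fit.W[j]
    if fit.method == "smml":
        # the pooled one-stage model lives on the global clock
        t_glob = _default_offsets(data)[s] + t_local - float(st.times[0])
        x = st.genotype
        genetic = x @ fit.W[0] + t_glob * (x @ fit.V[0])
        if unseen:
            a = fit.A.mean(axis=0)
            b = fit.B.mean(axis=0)
            return genetic + a + t_glob * b
        pos = {sid: i for i, sid in enumerate(fit.subject_ids)}
        rows = np.array([pos[sid] for sid in st.subject_ids])
        return genetic + fit.A[rows] + t_glob * fit.B[rows]
    if unseen:
        return predict(fit, data, s, t_local, genotype=st.genotype,
                       population_aging=True)
    return predict(fit, data, s, t_local)


def stage_rmse(
    fit: MscolorFit | SmtrFit,
    data: LongitudinalDataset,
    *,
    unseen: bool = True,
) -> np.ndarray:
    """Per-stage RMSE, averaged over subject x QT trajectory vectors.

    Each subject/QT trajectory over a stage's visits is scored by
    :func:`rmse` and the values are averaged.  ``unseen=True`` predicts with
    population-mean aging effects (held-out subjects); ``unseen=False`` uses
    the fitted subject-level effects (training fit quality).
    """
    out = []
    for s, st in enumerate(data.stages):
        pred = np.stack([
            _predict_stage_visit(fit, data, s, k, unseen=unseen)
            for k in range(st.n_visits)
        ])
        sq = ((st.qts - pred) ** 2).mean(axis=0)  # (n, c) per-trajectory MSE
        out.append(float(np.sqrt(sq).mean()))
    return np.array(out)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Nested-CV results: one row of fold-level RMSEs plus the selections."""

    method: str
    grid: list
    fold_test_rmse: np.ndarray       # (k_outer, L) per-stage test RMSE
    fold_train_rmse: np.ndarray      # (k_outer, L) per-stage train RMSE
    selected: list                   # chosen lam per outer fold
    seed: int
    mean_test_rmse: float = field(init=False)
    sd_test_rmse: float = field(init=False)

    def __post_init__(self) -> None:
        overall = self.fold_test_rmse.mean(axis=1)
        self.mean_test_rmse = float(overall.mean())
        self.sd_test_rmse = float(overall.std(ddof=1)) if len(overall) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        L = self.fold_test_rmse.shape[1]
        rows = []
        for s in range(L):
            rows.append({
                "stage": s + 1,
                "test_rmse_mean": float(self.fold_test_rmse[:, s].mean()),
                "test_rmse_sd": float(self.fold_test_rmse[:, s].std(ddof=1))
                if self.fold_test_rmse.shape[0] > 1 else 0.0,
                "train_rmse_mean": float(self.fold_train_rmse[:, s].mean()),
            })
        rows.append({"stage": "average",
                     "test_rmse_mean": self.mean_test_rmse,
                     "test_rmse_sd": self.sd_test_rmse,
                     "train_rmse_mean": float(self.fold_train_rmse.mean())})
        return pd.DataFrame(rows)


def _fold_assignment(ids: list[str], k: int, seed: int) -> list[np.ndarray]:
    """Deterministic disjoint k-fold split of subject ids."""
    ids = sorted(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [perm[f::k] for f in range(k)]


def _subset(data: LongitudinalDataset, keep: set[str]) -> LongitudinalDataset:
    return data.subset(sorted(keep))


def _standardized_pair(train, test):
    scalers = fit_dataset_scalers(train)
    return apply_dataset_scalers(train, scalers), apply_dataset_scalers(test, scalers)


def _grid_key(lam) -> tuple[float, float]:
    return (float(lam), float(lam)) if np.isscalar(lam) else (float(lam[0]), float(lam[1]))


def select_lambda_cv(
    data: LongitudinalDataset,
    summary: HarmonizedSummary | None,
    method: str,
    grid: list,
    k: int = 5,
    seed: int = 0,
    base_config: SolverConfig | None = None,
):
    """Pick the grid entry minimizing mean validation RMSE over ``k`` folds.

    Ties (within 1e-12 relative) break toward the larger penalty, i.e. the
    sparser model.  Standardization is refit on each fold's training part.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    if len(grid) == 1:
        return grid[0]
    folds = _fold_assignment(data.registry, k, seed)
    ids = np.array(sorted(data.registry))
    scores = np.zeros(len(grid))
    for f in range(k):
        va = set(ids[folds[f]])
        tr = set(ids) - va
        ds_tr, ds_va = _standardized_pair(_subset(data, tr), _subset(data, va))
        for gi, lam in enumerate(grid):
            fit = fit_method(ds_tr, summary, method, lam, base_config)
            scores[gi] += stage_rmse(fit, ds_va, unseen=True).mean()
    best = scores.min()
    tol = 1e-12 * max(1.0, abs(best))
    tied = [lam for gi, lam in enumerate(grid) if scores[gi] <= best + tol]
    return max(tied, key=lambda lam: sum(_grid_key(lam)))


def nested_cv(
    data: LongitudinalDataset,
    summary: HarmonizedSummary | None = None,
    method: str = "mscolor",
    grid: list | None = None,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
    base_config: SolverConfig | None = None,
) -> CvReport:
    """Nested subject-level CV: inner folds select lam, outer folds score it.

    The default grid is the decade ladder ``10^i`` for ``i = -3..3`` applied
    to both penalty weights jointly.  Within each outer fold the QT and
    genotype standardization is fit on the training subjects only.
    """
    grid = grid if grid is not None else [10.0 ** i for i in range(-3, 4)]
    if not grid:
        raise ValueError("grid must be nonempty")
    for st in data.stages:
        if st.n_subjects < k_outer:
            raise ValueError(
                f"stage {st.stage_index} has {st.n_subjects} subjects; "
                f"need at least k_outer={k_outer}"
            )
    folds = _fold_assignment(data.registry, k_outer, seed)
    ids = np.array(sorted(data.registry))
    L = data.n_stages
    test_rmse = np.zeros((k_outer, L))
    train_rmse = np.zeros((k_outer, L))
    selected = []
    for f in range(k_outer):
        te = set(ids[folds[f]])
        tr = set(ids) - te
        ds_tr_raw = _subset(data, tr)
        lam = select_lambda_cv(ds_tr_raw, summary, method, grid, k=k_inner,
                               seed=seed + 1 + f, base_config=base_config)
        selected.append(lam)
        ds_tr, ds_te = _standardized_pair(ds_tr_raw, _subset(data, te))
        fit = fit_method(ds_tr, summary, method, lam, base_config)
        test_rmse[f] = stage_rmse(fit, ds_te, unseen=True)
        train_rmse[f] = stage_rmse(fit, ds_tr, unseen=False)
    return CvReport(method=method, grid=list(grid), fold_test_rmse=test_rmse,
                    fold_train_rmse=train_rmse, selected=selected, seed=seed)


# ---------------------------------------------------------------------------
# SNP selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-SNP weight scores, ranking, and (optionally) recovery metrics."""

    snp_ids: list[str]
    scores: np.ndarray                  # aggregate per-SNP score
    block_scores: pd.DataFrame          # per stage / block component scores
    ranking: list[str]                  # snp ids, best first
    top_k: int
    auc: float | None = None
    precision_at_k: float | None = None
    auc_undefined: bool = False

    def top(self) -> list[str]:
        return self.ranking[: self.top_k]


def selection_metrics(
    fits: MscolorFit | SmtrFit | list,
    truth: SimTruth | None = None,
    top_k: int = 10,
) -> SelectionReport:
    """Score SNPs by their learned weights, averaged across fold fits.

    For each fit and stage the row-max absolute coefficient of the intercept
    block (joint GWAS effects stacked with W when present) and the slope
    block (with V) is taken; block scores are means across fits; the
    aggregate per-SNP score is the max over stages and blocks.  With a known
    causal support the report carries ROC AUC and precision@top_k.
    """
    if not isinstance(fits, list):
        fits = [fits]
    if not fits:
        raise ValueError("need at least one fit")
    snp_ids = fits[0].snp_ids
    d = len(snp_ids)

    def _blocks(fit):
        out = {}
        if isinstance(fit, SmtrFit):
            out[("pooled", "intercept")] = np.abs(fit.stacked).max(axis=1)
            return out
        for s, (w, v) in enumerate(zip(fit.W, fit.V)):
            us = fit.u[s][:, None] if fit.u is not None else np.empty((d, 0))
            out[(f"stage{s + 1}", "intercept")] = np.abs(
                np.concatenate([us, w], axis=1)).max(axis=1)
            out[(f"stage{s + 1}", "slope")] = np.abs(
                np.concatenate([us, v], axis=1)).max(axis=1)
        return out

    acc: dict = {}
    for fit in fits:
        if fit.snp_ids != snp_ids:
            raise ValueError("fits disagree on SNP ids")
        for key, val in _blocks(fit).items():
            acc.setdefault(key, []).append(val)
    block_scores = pd.DataFrame(
        {f"{stage}_{blk}": np.mean(vals, axis=0) for (stage, blk), vals in acc.items()},
        index=snp_ids,
    )
    scores = block_scores.to_numpy().max(axis=1)
    order = np.argsort(-scores, kind="stable")
    ranking = [snp_ids[i] for i in order]

    auc = prec = None
    undefined = False
    if truth is not None:
        support = np.asarray(truth.causal_support, dtype=bool)
        if len(support) != d:
            raise ValueError("truth support length does not match SNP count")
        if np.all(scores == 0) or support.all() or not support.any():
            undefined = True
        else:
            # rank-based (Mann-Whitney) AUC
            ranks = scipy.stats.rankdata(scores)
            n1 = int(support.sum())
            n0 = d - n1
            auc = float((ranks[support].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
            prec = float(support[order[:top_k]].sum() / top_k)
    return SelectionReport(snp_ids=list(snp_ids), scores=scores,
                           block_scores=block_scores, ranking=ranking,
                           top_k=top_k, auc=auc, precision_at_k=prec,
                           auc_undefined=undefined)


# ---------------------------------------------------------------------------
# progression statistics
# ---------------------------------------------------------------------------

_BANDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_band(p: float) -> str:
    """Conventional star banding: ns, * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    if not 0 <= p <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    for thresh, stars in _BANDS:
        if p <= thresh:
            return stars
    return "ns"


def _subject_slopes(fit: MscolorFit, data: LongitudinalDataset, s: int) -> pd.DataFrame:
    """Fitted per-subject QT slopes for stage index ``s`` (rows = subjects)."""
    st = data.stages[s]
    additive = fit.method == "smml"
    g1 = 1.0 if additive else fit.config.gamma
    g2 = 1.0 if additive else 1.0 - fit.config.gamma
    _, b = fit.stage_aging(data, s)
    slope = g1 * (st.genotype @ fit.V[s]) + g2 * b
    return pd.DataFrame(slope, index=st.subject_ids, columns=st.qt_names)


def _subject_intercepts(fit: MscolorFit, data: LongitudinalDataset, s: int) -> pd.DataFrame:
    st = data.stages[s]
    additive = fit.method == "smml"
    g1 = 1.0 if additive else fit.config.gamma
    g2 = 1.0 if additive else 1.0 - fit.config.gamma
    a, _ = fit.stage_aging(data, s)
    icept = g1 * (st.genotype @ fit.W[s]) + g2 * a
    return pd.DataFrame(icept, index=st.subject_ids, columns=st.qt_names)


def stage_slope_tests(
    fit: MscolorFit,
    data: LongitudinalDataset,
    grouping: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-sample t-tests on fitted per-subject slope distributions.

    Without ``grouping``: every pair of stages is compared, per QT and for
    the QT average.  With ``grouping`` (e.g. a numeric-coded diagnosis
    series indexed by subject id): every pair of groups is compared within
    each stage.  Returns columns (comparison, qt, t, p, band).
    """
    slopes = [_subject_slopes(fit, data, s) for s in range(data.n_stages)]
    rows = []

    def _add(label, qt, a, b):
        t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        rows.append({"comparison": label, "qt": qt, "t": float(t),
                     "p": float(p), "band": significance_band(float(p))})

    qt_names = data.qt_names
    if grouping is None:
        for i in range(data.n_stages):
            for j in range(i + 1, data.n_stages):
                label = f"stage{i + 1} vs stage{j + 1}"
                for qt in qt_names:
                    _add(label, qt, slopes[i][qt].to_numpy(), slopes[j][qt].to_numpy())
                _add(label, "average",
                     slopes[i].mean(axis=1).to_numpy(), slopes[j].mean(axis=1).to_numpy())
    else:
        grouping = grouping.dropna()
        levels = sorted(grouping.unique())
        for s in range(data.n_stages):
            sl = slopes[s]
            common = [i for i in sl.index if i in grouping.index]
            gvals = grouping.loc[common]
            for gi in range(len(levels)):
                for gj in range(gi + 1, len(levels)):
                    ga = [i for i in common if gvals[i] == levels[gi]]
                    gb = [i for i in common if gvals[i] == levels[gj]]
                    if len(ga) < 2 or len(gb) < 2:
                        continue
                    label = f"stage{s + 1}: group {levels[gi]} vs {levels[gj]}"
                    for qt in qt_names:
                        _add(label, qt, sl.loc[ga, qt].to_numpy(), sl.loc[gb, qt].to_numpy())
                    _add(label, "average",
                         sl.loc[ga].mean(axis=1).to_numpy(), sl.loc[gb].mean(axis=1).to_numpy())
    return pd.DataFrame(rows)


def trajectory_correlations(
    fit: MscolorFit,
    data: LongitudinalDataset,
    score_names: list[str],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson correlations of per-subject trajectory summaries with scores.

    For each stage, the QT-averaged fitted slope and intercept of every
    subject are correlated (signed values) with each named numeric column of
    the covariate table.  Returns (stage, summary, score, r, p, band).
    """
    cov = covariates if covariates is not None else data.covariates
    if cov is None:
        raise ValueError("no covariate table with scores available")
    missing = [s for s in score_names if s not in cov.columns]
    if missing:
        raise KeyError(f"score column(s) not found: {missing}")
    rows = []
    for s in range(data.n_stages):
        summaries = {
            "slope": _subject_slopes(fit, data, s).mean(axis=1),
            "intercept": _subject_intercepts(fit, data, s).mean(axis=1),
        }
        for name, vals in summaries.items():
            common = [i for i in vals.index if i in cov.index]
            for score in score_names:
                sc = cov.loc[common, score].astype(float)
                r, p = scipy.stats.pearsonr(vals.loc[common].to_numpy(), sc.to_numpy())
                rows.append({"stage": s + 1, "summary": name, "score": score,
                             "r": float(r), "p": float(p),
                             "band": significance_band(float(p))})
    return pd.DataFrame(rows)


def anova_snp_effect(
    genotype: np.ndarray,
    diagnosis: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Covariate-adjusted one-way ANOVA of a SNP's effect on diagnosis.

    Fits a linear model of numeric-coded diagnosis on the genotype dosage as
    a categorical factor plus the covariate columns (e.g. age, gender,
    handedness, education) and returns the partial F statistic and p-value
    of the genotype factor.
    """
    import statsmodels.api as sm

    g = np.asarray(genotype, dtype=float)
    y = np.asarray(diagnosis, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("genotype and diagnosis must be matching 1-d arrays")
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("genotype column has no variation")
    base = np.ones((len(g), 1))
    if covariates is not None:
        cmat = np.asarray(covariates, dtype=float)
        if cmat.ndim == 1:
            cmat = cmat[:, None]
        base = np.concatenate([base, cmat], axis=1)
    dummies = np.stack([(g == lv).astype(float) for lv in levels[1:]], axis=1)
    full = np.concatenate([base, dummies], axis=1)
    fit0 = sm.OLS(y, base).fit()
    fit1 = sm.OLS(y, full).fit()
    df_num = fit0.df_resid - fit1.df_resid
    if fit1.df_resid <= 0:
        raise ValueError("not enough observations for the adjusted model")
    f = float((fit0.ssr - fit1.ssr) / df_num / (fit1.ssr / fit1.df_resid))
    p = float(scipy.stats.f.sf(f, df_num, fit1.df_resid))
    return f, p


# ---------------------------------------------------------------------------
# replicate studies over simulated cohorts
# ---------------------------------------------------------------------------

def support_recovery_replicate(
    seed: int,
    cfg: SimConfig | None = None,
    grid: list | None = None,
    k_inner: int = 5,
    base_config: SolverConfig | None = None,
) -> dict:
    """One seeded support-recovery run of the collaborative model.

    Simulates a study, picks the penalty weight by subject-level CV on the
    decade grid, refits on the full cohort, and scores the causal support
    and the stage slope profile.  Returns auc, precision_at_k and whether
    the middle stage has the largest fitted slope norm.
    """
    study = simulate_study(cfg, seed=seed)
    grid = grid if grid is not None else [10.0 ** i for i in range(-3, 4)]
    lam = select_lambda_cv(study.data, study.harmonized, "mscolor", grid,
                           k=k_inner, seed=seed, base_config=base_config)
    fit = fit_method(study.data, study.harmonized, "mscolor", lam, base_config)
    report = selection_metrics(fit, study.truth, top_k=study.config.n_causal)
    v_norms = [float(np.sqrt((v ** 2).sum())) for v in fit.V]
    return {
        "seed": seed,
        "lambda": lam,
        "auc": report.auc,
        "precision_at_k": report.precision_at_k,
        "v_norms": v_norms,
        "stage2_slope_largest": bool(int(np.argmax(v_norms)) ==
                                     int(np.argmax(study.config.stage_slope_profile))),
    }


def rmse_ordering_replicate(
    seed: int,
    cfg: SimConfig | None = None,
    methods: tuple = ("mscolor", "msmml", "smml"),
    grid: list | None = None,
    test_fraction: float = 0.2,
    k_inner: int = 3,
    base_config: SolverConfig | None = None,
) -> dict:
    """One seeded train/test comparison of the methods' mean test RMSE.

    Simulates a study, holds out ``test_fraction`` of the subjects, selects
    each method's penalty by inner CV on the training part, and reports each
    method's mean per-stage test RMSE on held-out subjects.
    """
    study = simulate_study(cfg, seed=seed)
    grid = grid if grid is not None else [10.0 ** i for i in range(-3, 4)]
    ids = np.array(sorted(study.data.registry))
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(ids))))
    test_ids = set(rng.choice(ids, size=n_test, replace=False))
    train_ids = set(ids) - test_ids
    ds_tr_raw = _subset(study.data, train_ids)
    ds_tr, ds_te = _standardized_pair(ds_tr_raw, _subset(study.data, test_ids))
    out = {"seed": seed}
    for method in methods:
        summary = study.harmonized if method == "mscolor" else None
        lam = select_lambda_cv(ds_tr_raw, summary, method, grid, k=k_inner,
                               seed=seed + 1, base_config=base_config)
        fit = fit_method(ds_tr, summary, method, lam, base_config)
        out[method] = float(stage_rmse(fit, ds_te, unseen=True).mean())
        out[f"{method}_lambda"] = lam
    return out
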