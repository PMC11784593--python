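"""Comparison methods fitted under the same data model and harness.

Three controls bracket the collaborative multi-stage model:

* **sMTR** — sparse multi-task regression: one coefficient matrix per time
  point, group-sparse (l_2,1) across tasks, no aging effects and no notion of
  a trajectory.  It ranks SNPs but cannot model progression.
* **sMML** — one-stage sparse multi-task mixed-effects longitudinal
  regression: a single intercept/slope pair per subject and per SNP over the
  whole follow-up, Z_k = A + X W + (B + X V) t_k, with l_2,1 penalties.
* **MSMML** — the multi-stage model with per-stage aging effects and the
  l_inf,1 penalty but *without* GWAS summary statistics; isolates the
  contribution of the collaborative term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import LongitudinalDataset, StageData
from .solver import MscolorFit, SolverConfig, _fit_engine, _solve_spd, reweight

__all__ = ["fit_smtr", "fit_smml", "fit_msmml", "pool_stages", "SmtrFit"]


def pool_stages(data: LongitudinalDataset, *, offsets: list[float] | None = None
                ) -> LongitudinalDataset:
    """Flatten a multi-stage dataset into a one-stage view for sMTR/sMML.

    Every (stage, visit) pair becomes one observation of a single long
    follow-up; visit times are shifted by per-stage ``offsets`` (default: the
    cumulative spans, so stages are laid end to end when no explicit global
    schedule is known).  Only subjects present in *all* stages are retained,
    because the one-stage methods assume a common subject set across time
    points.  Duplicate global times are allowed (two stage windows may cover
    the same month) and are treated as repeated measures.
    """
    common = set(data.stages[0].subject_ids)
    for st in data.stages[1:]:
        common &= set(st.subject_ids)
    if not common:
        raise ValueError("no subjects present in every stage; cannot pool")
    subj = sorted(common)

    if offsets is None:
        offsets = []
        acc = 0.0
        for st in data.stages:
            offsets.append(acc)
            acc += float(st.times[-1] - st.times[0]) if st.n_visits > 1 else 1.0

    slices = []
    times = []
    geno = None
    for st, off in zip(data.stages, offsets):
        sub = st.subset(subj)
        # subset preserves stage row order; re-index rows to the sorted subject list
        pos = {s: i for i, s in enumerate(sub.subject_ids)}
        idx = [pos[s] for s in subj]
        g = sub.genotype[idx]
        if geno is None:
            geno = g
        for k, t in enumerate(sub.times):
            slices.append(sub.qts[k][idx])
            times.append(off + float(t) - float(sub.times[0]))
    order = np.argsort(np.asarray(times), kind="stable")
    qts = np.stack([slices[i] for i in order])
    tvec = np.asarray(times)[order]
    # strictly-increasing check is for user-built stages; pooled windows may
    # legitimately revisit a month, so nudge exact ties by a negligible epsilon
    for i in range(1, len(tvec)):
        if tvec[i] <= tvec[i - 1]:
            tvec[i] = tvec[i - 1] + 1e-9
    stage = StageData(1, subj, geno, qts, tvec, data.stages[0].qt_names,
                      data.stages[0].snp_ids)
    return LongitudinalDataset(stages=[stage], covariates=data.covariates)


@dataclass
class SmtrFit:
    """Per-time-point coefficient matrices with a shared group-sparse support."""

    subject_ids: list[str]
    snp_ids: list[str]
    qt_names: list[str]
    W: list[np.ndarray]  # one (d, c) block per pooled time point
    times: np.ndarray
    lam: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    method: str = "smtr"

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate(self.W, axis=1)


def fit_smtr(
    data: LongitudinalDataset,
    lam: float,
    *,
    max_iter: int = 200,
    tol: float = 1e-5,
    delta: float = 1e-8,
) -> SmtrFit:
    """Fit min_W sum_k ||Y_k - X W_k||_F^2 + lam * ||[W_1 ... W_m]||_{2,1}.

    Solved by iteratively reweighted ridge: the l_2,1 penalty over stacked
    rows gives a shared diagonal weight D, and each task solves
    (X'X + lam D) W_k = X'Y_k.  The logged surrogate uses the same
    frozen-weight completion as the main solver and is non-increasing.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    pooled = pool_stages(data) if data.n_stages > 1 else data
    st = pooled.stages[0]
    x = st.genotype
    g = x.T @ x
    d = x.shape[1]
    m = st.n_visits
    xty = [x.T @ st.qts[k] for k in range(m)]
    # identity-weight ridge warm start (same rationale as the main engine:
    # reweighting a zero iterate pins it at the smoothing floor)
    warm = g + lam * np.eye(d) if lam > 0 else g
    W = [_solve_spd(warm, xty[k], "sMTR W") for k in range(m)]

    def objective(wlist):
        smooth = sum(float(((st.qts[k] - x @ wlist[k]) ** 2).sum()) for k in range(m))
        stack = np.concatenate(wlist, axis=1)
        sq = (stack * stack).sum(axis=1)
        mu = np.maximum(np.sqrt(sq), delta)
        return smooth + lam * float((sq / (2 * mu) + mu / 2).sum())

    trace = [objective(W)]
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        prev = [wk.copy() for wk in W]
        dvec = reweight(np.concatenate(W, axis=1), delta, norm="l21")
        mat = g + lam * np.diag(dvec) if lam > 0 else g
        for k in range(m):
            W[k] = _solve_spd(mat, xty[k], "sMTR W")
        obj = objective(W)
        if obj > trace[-1] - 1e-12 * max(1.0, abs(trace[0])):
            W = prev
            converged = True
            n_iter = it
            break
        trace.append(obj)
        if max(float(np.abs(W[k] - prev[k]).max()) for k in range(m)) <= tol:
            converged = True
            break
    return SmtrFit(
        subject_ids=st.subject_ids,
        snp_ids=st.snp_ids,
        qt_names=st.qt_names,
        W=W,
        times=st.times,
        lam=lam,
        objective_trace=np.array(trace),
        converged=converged,
        n_iter=n_iter,
    )


def fit_smml(
    data: LongitudinalDataset,
    lambda1: float,
    lambda2: float,
    config: SolverConfig | None = None,
) -> MscolorFit:
    """One-stage mixed-effects fit Z_k = A + XW + (B + XV) t_k with l_2,1 penalties.

    Multi-stage input is first pooled into a single long follow-up (subjects
    present in every stage).  The additive parameterization carries no gamma
    weight, matching the model as defined for a single monotone trajectory.
    """
    pooled = pool_stages(data) if data.n_stages > 1 else data
    base = config or SolverConfig()
    cfg = replace(base, lambda_p=lambda1, lambda_q=lambda2, tau=0.0, share_aging=True)
    return _fit_engine(pooled, None, cfg, method="smml", penalty="l21",
                       additive=True, use_gwas=False)


def fit_msmml(
    data: LongitudinalDataset,
    lambda1: float,
    lambda2: float,
    gamma: float = 0.5,
    config: SolverConfig | None = None,
) -> MscolorFit:
    """Multi-stage mixed-effects fit without GWAS summary statistics.

    Identical to the collaborative model except the u_s blocks are absent
    (the l_inf,1 penalty acts on W_s and V_s alone) and the aging effects are
    per stage.
    """
    base = config or SolverConfig()
    cfg = replace(base, gamma=gamma, lambda_p=lambda1, lambda_q=lambda2,
                  tau=0.0, share_aging=False)
    return _fit_engine(data, None, cfg, method="msmml", penalty="linf",
                       additive=False, use_gwas=False)
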