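"""Alternating closed-form solver for multi-stage collaborative regression.

Model
-----
For stage s with genotype X_s (n_s x d), QT slices Z_ks (n_s x c) at visit
times t_ks, the fitted trajectory is

    gamma * (X_s W_s + X_s V_s t_ks) + (1 - gamma) * (A_s + B_s t_ks),

where W_s / V_s carry genetic intercept/slope effects, A / B carry per-subject
population aging effects (shared across stages and row-selected through the
subject registry, or per-stage), and gamma in [0, 1] balances the two.  GWAS
summary statistics enter through per-stage joint effects u_s coupled to W_s
and V_s by an l_inf,1 penalty on the stacked matrices P_s = [u_s W_s] and
Q_s = [u_s V_s]: SNP rows are selected jointly across the longitudinal tasks
and the external GWAS, which lets a small imaging cohort borrow power from a
large association study.

Because y'y of the GWAS phenotype is unavailable from summary data, the GWAS
data-fit term ||y - X u_s||^2 is evaluated up to that additive constant as
(n_ref - 1) * (u_s' Sigma u_s - 2 u_s' beta) (+ the numerical ridge term).

Optimization
------------
All blocks have closed-form minimizers given the others; the l_inf,1 penalty
is handled by diagonal reweighting with entries 1 / (2 max(row-max, delta)).
Each iteration updates A, B, then per stage u_s, W_s, V_s, refreshing the
weights before each solve.  The logged surrogate objective replaces each
penalty row by its frozen-weight quadratic completion
``||p||^2 / (2 mu) + mu / 2`` with ``mu = max(row-max, delta)``, which the
closed-form updates minimize exactly blockwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .data_model import LongitudinalDataset, StageData
from .gwas import HarmonizedSummary

__all__ = [
    "SolverConfig",
    "MscolorFit",
    "linf1_norm",
    "l21_norm",
    "reweight",
    "surrogate_objective",
    "fit_mscolor",
    "predict",
]


# ---------------------------------------------------------------------------
# penalties and reweighting
# ---------------------------------------------------------------------------

def linf1_norm(p: np.ndarray) -> float:
    """Sum over rows of the maximum absolute entry: sum_i max_j |P_ij|."""
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    return float(np.abs(p).max(axis=1).sum())


def l21_norm(w: np.ndarray) -> float:
    """Sum over rows of the row Euclidean norm: sum_i ||W_i||_2."""
    w = np.asarray(w, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    return float(np.sqrt((w * w).sum(axis=1)).sum())


def reweight(p: np.ndarray, delta: float, *, norm: str = "linf") -> np.ndarray:
    """Diagonal reweighting entries 1 / (2 max(rho_i, delta)).

    ``rho_i`` is the row maximum absolute entry for the l_inf,1 penalty or the
    row Euclidean norm for the l_2,1 penalty; ``delta > 0`` floors zero rows.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if norm == "linf":
        rho = np.abs(p).max(axis=1)
    elif norm == "l21":
        rho = np.sqrt((p * p).sum(axis=1))
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return 1.0 / (2.0 * np.maximum(rho, delta))


def _penalty_terms(p: np.ndarray, delta: float, norm: str) -> tuple[float, float]:
    """(surrogate completion value, true penalty value) for one matrix."""
    if p.ndim == 1:
        p = p[:, None]
    sq = (p * p).sum(axis=1)
    if norm == "linf":
        rho = np.abs(p).max(axis=1)
    else:
        rho = np.sqrt(sq)
    mu = np.maximum(rho, delta)
    surrogate = float((sq / (2.0 * mu) + mu / 2.0).sum())
    return surrogate, float(rho.sum())


# ---------------------------------------------------------------------------
# configuration and fit containers
# ---------------------------------------------------------------------------

@dataclass
class SolverConfig:
    """Hyperparameters and numerical settings for the alternating solver.

    ``lambda_p`` / ``lambda_q`` may be scalars (shared across stages) or
    per-stage sequences.  ``tau`` weights the GWAS data-fit term (1 = the
    model as defined; 0 removes the collaborative term).  ``ridge`` is added
    to the LD matrix diagonal in the u_s solve.
    """

    gamma: float = 0.5
    lambda_p: float | Sequence[float] = 1.0
    lambda_q: float | Sequence[float] = 1.0
    max_iter: int = 200
    tol: float = 1e-5
    smoothing_delta: float = 1e-8
    init_scheme: str = "warm"
    seed: int = 0
    ridge: float = 1e-3
    tau: float = 1.0
    share_aging: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.tol <= 0 or self.smoothing_delta <= 0:
            raise ValueError("tol and smoothing_delta must be positive")
        if self.init_scheme not in ("warm", "zeros", "random"):
            raise ValueError("init_scheme must be 'warm', 'zeros' or 'random'")

    def stage_lambdas(self, n_stages: int) -> tuple[np.ndarray, np.ndarray]:
        lp = np.broadcast_to(np.asarray(self.lambda_p, dtype=float), (n_stages,)).copy()
        lq = np.broadcast_to(np.asarray(self.lambda_q, dtype=float), (n_stages,)).copy()
        if (lp < 0).any() or (lq < 0).any():
            raise ValueError("lambda_p and lambda_q must be nonnegative")
        return lp, lq


@dataclass
class MscolorFit:
    """Fitted parameters, objective traces, and convergence metadata.

    ``A`` and ``B`` are indexed by the subject registry when aging effects are
    shared (``subject_ids`` gives the row labels); in per-stage mode ``A_s`` /
    ``B_s`` hold one block per stage indexed by that stage's subjects.
    """

    method: str
    subject_ids: list[str]
    snp_ids: list[str]
    qt_names: list[str]
    A: np.ndarray
    B: np.ndarray
    W: list[np.ndarray]
    V: list[np.ndarray]
    u: list[np.ndarray] | None
    A_s: list[np.ndarray] | None
    B_s: list[np.ndarray] | None
    config: SolverConfig
    objective_trace: np.ndarray
    true_objective_trace: np.ndarray
    converged: bool
    n_iter: int
    extras: dict = field(default_factory=dict)

    def stage_aging(self, data: LongitudinalDataset, s: int) -> tuple[np.ndarray, np.ndarray]:
        """(A_s, B_s) rows for the subjects of stage index ``s`` (0-based)."""
        if self.A_s is not None and self.B_s is not None:
            return self.A_s[s], self.B_s[s]
        rows = data.registry_rows(data.stages[s])
        return self.A[rows], self.B[rows]


# ---------------------------------------------------------------------------
# internal engine
# ---------------------------------------------------------------------------

class _StageWork:
    """Per-stage sufficient statistics reused across iterations."""

    __slots__ = ("X", "Z", "t", "rows", "G", "Zsum", "Ztsum", "XtZ0", "XtZ1",
                 "m", "T", "T2", "n")

    def __init__(self, stage: StageData, rows: np.ndarray) -> None:
        self.X = stage.genotype
        self.Z = stage.qts
        self.t = stage.times
        self.rows = rows
        self.G = self.X.T @ self.X
        self.Zsum = self.Z.sum(axis=0)
        self.Ztsum = np.tensordot(self.t, self.Z, axes=1)
        self.XtZ0 = self.X.T @ self.Zsum
        self.XtZ1 = self.X.T @ self.Ztsum
        self.m = len(self.t)
        self.T = float(self.t.sum())
        self.T2 = float((self.t ** 2).sum())
        self.n = stage.n_subjects


def _solve_spd(m: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(m, check_finite=False)
        return scipy.linalg.cho_solve((c, low), rhs, check_finite=False)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular system in the {what} update; use a positive penalty "
            "(lambda > 0) or a larger smoothing delta/ridge"
        ) from err


def _fit_engine(
    data: LongitudinalDataset,
    summary: HarmonizedSummary | None,
    config: SolverConfig,
    *,
    method: str = "mscolor",
    penalty: str = "linf",
    additive: bool = False,
    use_gwas: bool = True,
) -> MscolorFit:
    """Shared alternating-minimization engine.

    ``additive=True`` drops the gamma weighting (the one-stage mixed-effects
    parameterization Z = A + XW + (B + XV) t); otherwise the collaborative
    gamma-weighted form is used.  ``use_gwas=False`` removes the u_s blocks
    entirely (the penalty then acts on W_s and V_s alone).
    """
    L = data.n_stages
    d = len(data.snp_ids)
    c = len(data.qt_names)
    delta = config.smoothing_delta
    lam_p, lam_q = config.stage_lambdas(L)
    g1 = 1.0 if additive else config.gamma
    g2 = 1.0 if additive else 1.0 - config.gamma
    share = config.share_aging
    tau = config.tau if use_gwas else 0.0

    use_gwas = use_gwas and summary is not None
    if use_gwas:
        if summary.snp_ids != data.snp_ids:
            raise ValueError("summary statistics are not harmonized to the dataset SNPs")
        sigma = summary.sigma
        beta = summary.beta
        n_ref = summary.n_ref
        gwas_scale = tau * (n_ref - 1)
    else:
        sigma = beta = None
        gwas_scale = 0.0

    works = [_StageWork(st, data.registry_rows(st)) for st in data.stages]
    N = len(data.registry)

    rng = np.random.default_rng(config.seed)

    def _init(shape):
        if config.init_scheme == "random":
            return 0.01 * rng.standard_normal(shape)
        return np.zeros(shape)

    W = [_init((d, c)) for _ in range(L)]
    V = [_init((d, c)) for _ in range(L)]
    u = [np.zeros(d) for _ in range(L)] if use_gwas else None

    if share:
        A = np.zeros((N, c))
        B = _init((N, c))
        A_s = B_s = None
        # per-registry-subject observation counts and time sums
        Nreg = np.zeros(N)
        Treg = np.zeros(N)
        T2reg = np.zeros(N)
        for w in works:
            Nreg[w.rows] += w.m
            Treg[w.rows] += w.T
            T2reg[w.rows] += w.T2
    else:
        A = np.zeros((N, c))  # unused placeholders for the fit container
        B = np.zeros((N, c))
        A_s = [np.zeros((w.n, c)) for w in works]
        B_s = [_init((w.n, c)) for w in works]

    warned_static = False

    def _aging(si: int) -> tuple[np.ndarray, np.ndarray]:
        if share:
            return A[works[si].rows], B[works[si].rows]
        return A_s[si], B_s[si]

    def _stack(us_val, m1, m2=None):
        cols = [m1] if m2 is None else [m1, m2]
        if us_val is not None:
            cols = [us_val[:, None]] + cols
        return np.concatenate(cols, axis=1)

    def _objective() -> tuple[float, float]:
        smooth = 0.0
        for si, w in enumerate(works):
            asel, bsel = _aging(si)
            XW = w.X @ W[si]
            XV = w.X @ V[si]
            fit_vals = g1 * (XW[None] + w.t[:, None, None] * XV[None]) + g2 * (
                asel[None] + w.t[:, None, None] * bsel[None]
            )
            r = w.Z - fit_vals
            smooth += float((r * r).sum())
            if use_gwas:
                us = u[si]
                smooth += gwas_scale * float(
                    us @ sigma @ us - 2.0 * us @ beta + config.ridge * us @ us
                )
        sur = true = 0.0
        for si in range(L):
            us = u[si] if use_gwas else None
            for lam, block in ((lam_p[si], _stack(us, W[si])), (lam_q[si], _stack(us, V[si]))):
                sp, tp = _penalty_terms(block, delta, penalty)
                sur += lam * sp
                true += lam * tp
        return smooth + sur, smooth + true

    def _sweep(identity_weights: bool = False) -> None:
        """One full pass of block updates, mutating the parameter state.

        With ``identity_weights`` the diagonal reweighting is replaced by the
        identity (a plain ridge pass), used once as a warm start so the
        reweighting does not pin a zero initial iterate at the smoothing
        floor.
        """
        nonlocal A, B, warned_static

        # ---- aging effects A, B ------------------------------------------
        if g2 > 0:
            if share:
                S0 = np.zeros((N, c))
                S1 = np.zeros((N, c))
                for si, w in enumerate(works):
                    XW = w.X @ W[si]
                    XV = w.X @ V[si]
                    r0 = w.Zsum - g1 * (w.m * XW + w.T * XV)
                    r1 = w.Ztsum - g1 * (w.T * XW + w.T2 * XV)
                    np.add.at(S0, w.rows, r0)
                    np.add.at(S1, w.rows, r1)
                A = (S0 - g2 * B * Treg[:, None]) / (g2 * Nreg[:, None])
                movable = T2reg > 0
                if not movable.all() and not warned_static:
                    warnings.warn("subjects with all-zero visit times: B rows held fixed")
                    warned_static = True
                B_new = B.copy()
                B_new[movable] = (
                    S1[movable] - g2 * A[movable] * Treg[movable, None]
                ) / (g2 * T2reg[movable, None])
                B = B_new
            else:
                for si, w in enumerate(works):
                    XW = w.X @ W[si]
                    XV = w.X @ V[si]
                    r0 = w.Zsum - g1 * (w.m * XW + w.T * XV)
                    r1 = w.Ztsum - g1 * (w.T * XW + w.T2 * XV)
                    A_s[si] = (r0 - g2 * B_s[si] * w.T) / (g2 * w.m)
                    if w.T2 > 0:
                        B_s[si] = (r1 - g2 * A_s[si] * w.T) / (g2 * w.T2)

        # ---- per-stage genetic blocks ------------------------------------
        for si, w in enumerate(works):
            asel, bsel = _aging(si)
            if g2 > 0:
                XtA = w.X.T @ asel
                XtB = w.X.T @ bsel
            else:
                XtA = XtB = 0.0

            if use_gwas:
                # refresh D-tilde from the current P_s, Q_s, then solve u_s
                if tau > 0:
                    if identity_weights:
                        dp = dq = np.ones(d)
                    else:
                        dp = reweight(_stack(u[si], W[si]), delta, norm=penalty)
                        dq = reweight(_stack(u[si], V[si]), delta, norm=penalty)
                    m_u = sigma + np.diag(
                        (lam_p[si] * dp + lam_q[si] * dq) / gwas_scale
                    )
                    if config.ridge > 0:
                        m_u = m_u + config.ridge * np.eye(d)
                    u[si] = _solve_spd(m_u, beta, "u")
                else:
                    u[si] = np.zeros(d)

            if g1 > 0:
                us = u[si] if use_gwas else None
                dp = (np.ones(d) if identity_weights
                      else reweight(_stack(us, W[si]), delta, norm=penalty))
                rhs_w = g1 * (
                    w.XtZ0 - g1 * w.T * (w.G @ V[si]) - g2 * (w.m * XtA + w.T * XtB)
                )
                m_w = g1 * g1 * w.m * w.G + np.diag(lam_p[si] * dp)
                if lam_p[si] == 0:
                    m_w = m_w + 0.0  # may be singular; cho_factor will say so
                W[si] = _solve_spd(m_w, rhs_w, "W")

                dq = (np.ones(d) if identity_weights
                      else reweight(_stack(us, V[si]), delta, norm=penalty))
                rhs_v = g1 * (
                    w.XtZ1 - g1 * w.T * (w.G @ W[si]) - g2 * (w.T * XtA + w.T2 * XtB)
                )
                m_v = g1 * g1 * w.T2 * w.G + np.diag(lam_q[si] * dq)
                V[si] = _solve_spd(m_v, rhs_v, "V")

    if config.init_scheme == "warm":
        _sweep(identity_weights=True)

    trace = []
    true_trace = []
    obj0, tobj0 = _objective()
    trace.append(obj0)
    true_trace.append(tobj0)

    converged = False
    n_iter = 0
    for it in range(config.max_iter):
        n_iter = it + 1
        W_prev = [wk.copy() for wk in W]
        V_prev = [vk.copy() for vk in V]
        u_prev = [uk.copy() for uk in u] if use_gwas else None
        if share:
            A_prev, B_prev = A.copy(), B.copy()
        else:
            A_prev = [a.copy() for a in A_s]
            B_prev = [b.copy() for b in B_s]

        _sweep()
        obj, tobj = _objective()
        if not np.isfinite(obj):
            raise RuntimeError(
                f"objective became non-finite at iteration {n_iter} "
                f"(gamma={config.gamma}, lambda_p={lam_p}, lambda_q={lam_q})"
            )
        if obj > trace[-1] - 1e-12 * max(1.0, abs(trace[0])):
            # Surrogate stall: the reweighted updates can bounce near row-max
            # ties (the weight refresh is not an exact majorizer).  Revert to
            # the previous (no worse) iterate and stop; the logged trace stays
            # non-increasing.
            W, V = W_prev, V_prev
            if use_gwas:
                u = u_prev
            if share:
                A, B = A_prev, B_prev
            else:
                A_s, B_s = A_prev, B_prev
            converged = True
            n_iter = it
            break
        trace.append(obj)
        true_trace.append(tobj)

        dw = max(float(np.abs(W[si] - W_prev[si]).max()) for si in range(L))
        dv = max(float(np.abs(V[si] - V_prev[si]).max()) for si in range(L))
        if dw <= config.tol and dv <= config.tol:
            converged = True
            break

    return MscolorFit(
        method=method,
        subject_ids=list(data.registry),
        snp_ids=list(data.snp_ids),
        qt_names=list(data.qt_names),
        A=A,
        B=B,
        W=W,
        V=V,
        u=u,
        A_s=A_s,
        B_s=B_s,
        config=config,
        objective_trace=np.array(trace),
        true_objective_trace=np.array(true_trace),
        converged=converged,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit_mscolor(
    data: LongitudinalDataset,
    summary: HarmonizedSummary | None,
    config: SolverConfig | None = None,
) -> MscolorFit:
    """Fit the collaborative multi-stage model by alternating closed forms.

    ``summary`` must be harmonized to the dataset's SNPs (same ids and order);
    pass ``None`` (or ``config.tau == 0``) to fit without the GWAS term, which
    reduces the model to its multi-stage mixed-effects control.
    """
    config = config or SolverConfig()
    return _fit_engine(data, summary, config, method="mscolor",
                       penalty="linf", use_gwas=summary is not None)


def surrogate_objective(
    fit: MscolorFit,
    data: LongitudinalDataset,
    summary: HarmonizedSummary | None = None,
) -> float:
    """Recompute the smoothed surrogate objective at the fitted parameters.

    This is the quantity logged in ``fit.objective_trace``: the residual data
    term, the GWAS term up to the constant y'y, and the frozen-weight penalty
    completion for each row.
    """
    return _objective_at(
        data, summary, fit.config,
        A=fit.A, B=fit.B, W=fit.W, V=fit.V, u=fit.u,
        A_s=fit.A_s, B_s=fit.B_s,
        penalty="linf" if fit.method != "smml" else "l21",
        additive=fit.method == "smml",
    )[0]


def _objective_at(
    data: LongitudinalDataset,
    summary: HarmonizedSummary | None,
    config: SolverConfig,
    *,
    A, B, W, V, u, A_s=None, B_s=None,
    penalty: str = "linf",
    additive: bool = False,
) -> tuple[float, float]:
    """(surrogate, true) objective at arbitrary parameter values."""
    L = data.n_stages
    lam_p, lam_q = config.stage_lambdas(L)
    delta = config.smoothing_delta
    g1 = 1.0 if additive else config.gamma
    g2 = 1.0 if additive else 1.0 - config.gamma
    use_gwas = u is not None and summary is not None
    smooth = 0.0
    for si, st in enumerate(data.stages):
        if A_s is not None and B_s is not None:
            asel, bsel = A_s[si], B_s[si]
        else:
            rows = data.registry_rows(st)
            asel, bsel = A[rows], B[rows]
        XW = st.genotype @ W[si]
        XV = st.genotype @ V[si]
        t = st.times
        fit_vals = g1 * (XW[None] + t[:, None, None] * XV[None]) + g2 * (
            asel[None] + t[:, None, None] * bsel[None]
        )
        r = st.qts - fit_vals
        smooth += float((r * r).sum())
        if use_gwas:
            us = u[si]
            gwas_scale = config.tau * (summary.n_ref - 1)
            smooth += gwas_scale * float(
                us @ summary.sigma @ us - 2.0 * us @ summary.beta
                + config.ridge * us @ us
            )
    sur = true = 0.0
    for si in range(L):
        stack_u = u[si][:, None] if use_gwas else None
        for lam, m in ((lam_p[si], W[si]), (lam_q[si], V[si])):
            block = m if stack_u is None else np.concatenate([stack_u, m], axis=1)
            sp, tp = _penalty_terms(block, delta, penalty)
            sur += lam * sp
            true += lam * tp
    return smooth + sur, smooth + true


def predict(
    fit: MscolorFit,
    data: LongitudinalDataset,
    stage: int,
    t: float,
    *,
    genotype: np.ndarray | None = None,
    population_aging: bool = False,
) -> np.ndarray:
    """Predicted QT matrix for one stage at time ``t`` (months, stage-local).

    By default uses the stage's training genotypes and fitted per-subject
    aging effects.  With ``genotype`` given (unseen subjects) or
    ``population_aging=True``, the column means of A and B stand in for the
    subject-level aging effects.

    Parameters
    ----------
    stage
        0-based stage index.
    """
    if not 0 <= stage < data.n_stages:
        raise ValueError(f"unknown stage {stage}; dataset has {data.n_stages}")
    additive = fit.method == "smml"
    g1 = 1.0 if additive else fit.config.gamma
    g2 = 1.0 if additive else 1.0 - fit.config.gamma
    x = data.stages[stage].genotype if genotype is None else np.asarray(genotype, float)
    genetic = x @ fit.W[stage] + t * (x @ fit.V[stage])
    if population_aging or genotype is not None:
        # population means come from the fit's own aging blocks (the row
        # registry of `data` may differ from the training registry)
        if fit.A_s is not None and fit.B_s is not None:
            a_sel, b_sel = fit.A_s[stage], fit.B_s[stage]
        else:
            a_sel, b_sel = fit.A, fit.B
        a = np.broadcast_to(a_sel.mean(axis=0), genetic.shape)
        b = np.broadcast_to(b_sel.mean(axis=0), genetic.shape)
    else:
        a, b = fit.stage_aging(data, stage)
    return g1 * genetic + g2 * (a + t * b)
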