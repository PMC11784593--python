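"""Naive reference implementation of the alternating block updates.

Mirrors the documented update order of the production solver using plain
per-subject loops and generic linear solves.  Used by the tests as an
independent oracle: byte-level parity of the iterates, independent objective
evaluation, and finite-difference stationarity checks of each frozen block
subproblem.

Supported scope: shared aging effects, 0 < gamma < 1, with or without GWAS
summary statistics, l_inf,1 or l_2,1 penalty.
"""

from __future__ import annotations

import numpy as np


def row_weight(block: np.ndarray, delta: float, norm: str = "linf") -> np.ndarray:
    """Diagonal reweighting entries 1 / (2 max(rho_i, delta))."""
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    if norm == "linf":
        rho = np.abs(block).max(axis=1)
    else:
        rho = np.sqrt((block ** 2).sum(axis=1))
    return 1.0 / (2.0 * np.maximum(rho, delta))


def penalty_completion(block: np.ndarray, delta: float, norm: str) -> tuple[float, float]:
    """(frozen-weight surrogate value, true penalty value) of one matrix."""
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    sq = (block ** 2).sum(axis=1)
    if norm == "linf":
        rho = np.abs(block).max(axis=1)
    else:
        rho = np.sqrt(sq)
    mu = np.maximum(rho, delta)
    return float((sq / (2.0 * mu) + mu / 2.0).sum()), float(rho.sum())


def init_state(data, use_gwas: bool) -> dict:
    """All-zeros parameter state matching the engine's initialization."""
    L = data.n_stages
    d = len(data.snp_ids)
    c = len(data.qt_names)
    N = len(data.registry)
    return {
        "W": [np.zeros((d, c)) for _ in range(L)],
        "V": [np.zeros((d, c)) for _ in range(L)],
        "u": [np.zeros(d) for _ in range(L)] if use_gwas else None,
        "A": np.zeros((N, c)),
        "B": np.zeros((N, c)),
    }


def state_from_fit(fit) -> dict:
    return {
        "W": [w.copy() for w in fit.W],
        "V": [v.copy() for v in fit.V],
        "u": [uk.copy() for uk in fit.u] if fit.u is not None else None,
        "A": fit.A.copy(),
        "B": fit.B.copy(),
    }


def _stack(u, m):
    return m if u is None else np.column_stack([u, m])


def reference_objective(data, summary, config, st, penalty: str = "linf") -> tuple[float, float]:
    """(surrogate, true) objective evaluated with independent loops."""
    g1, g2 = config.gamma, 1.0 - config.gamma
    delta = config.smoothing_delta
    lam_p, lam_q = config.stage_lambdas(data.n_stages)
    W, V, u, A, B = st["W"], st["V"], st["u"], st["A"], st["B"]
    use_gwas = u is not None and summary is not None
    smooth = 0.0
    for si, stage in enumerate(data.stages):
        rows = data.registry_rows(stage)
        xw = stage.genotype @ W[si]
        xv = stage.genotype @ V[si]
        for k, t in enumerate(stage.times):
            resid = stage.qts[k] - g1 * (xw + t * xv) - g2 * (A[rows] + t * B[rows])
            smooth += float((resid ** 2).sum())
        if use_gwas:
            scale = config.tau * (summary.n_ref - 1)
            us = u[si]
            smooth += scale * float(us @ summary.sigma @ us - 2.0 * us @ summary.beta
                                    + config.ridge * us @ us)
    sur = true = 0.0
    for si in range(data.n_stages):
        us = u[si] if use_gwas else None
        for lam, mat in ((lam_p[si], W[si]), (lam_q[si], V[si])):
            sp, tp = penalty_completion(_stack(us, mat), delta, penalty)
            sur += lam * sp
            true += lam * tp
    return smooth + sur, smooth + true


def fd_max_grad(f, x: np.ndarray, h: float = 1e-4) -> float:
    """Max absolute central-difference partial derivative of ``f`` at ``x``.

    The block subproblems are quadratic, so the central difference is exact
    up to floating-point rounding for any step size.
    """
    flat = x.ravel()
    worst = 0.0
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        fp = f(x)
        flat[i] = orig - h
        fm = f(x)
        flat[i] = orig
        worst = max(worst, abs((fp - fm) / (2.0 * h)))
    return worst


def reference_sweep(data, summary, config, st, *, identity_weights: bool = False,
                    penalty: str = "linf", record: list | None = None) -> None:
    """One full pass of block updates, mutating ``st`` in place.

    With ``record`` a list, each block solve is followed by a
    finite-difference stationarity check of its frozen subproblem and
    ``(block_name, max_abs_fd_gradient)`` is appended.
    """
    g1, g2 = config.gamma, 1.0 - config.gamma
    delta = config.smoothing_delta
    d = len(data.snp_ids)
    lam_p, lam_q = config.stage_lambdas(data.n_stages)
    W, V, u = st["W"], st["V"], st["u"]
    A, B = st["A"], st["B"]
    N = A.shape[0]
    c = A.shape[1]
    use_gwas = u is not None and summary is not None

    # ---- aging effects A then B (closed forms per registry subject) -------
    S0 = np.zeros((N, c))
    S1 = np.zeros((N, c))
    cnt = np.zeros(N)
    tsum = np.zeros(N)
    t2sum = np.zeros(N)
    genetic = []  # per (stage, visit) genetic contribution, fixed within the sweep
    for si, stage in enumerate(data.stages):
        rows = data.registry_rows(stage)
        xw = stage.genotype @ W[si]
        xv = stage.genotype @ V[si]
        per_visit = []
        for k, t in enumerate(stage.times):
            gpart = g1 * (xw + t * xv)
            per_visit.append(gpart)
            S0[rows] += stage.qts[k] - gpart
            S1[rows] += t * (stage.qts[k] - gpart)
            cnt[rows] += 1.0
            tsum[rows] += t
            t2sum[rows] += t * t
        genetic.append(per_visit)

    def _aging_data_term(a_mat, b_mat):
        total = 0.0
        for si, stage in enumerate(data.stages):
            rows = data.registry_rows(stage)
            for k, t in enumerate(stage.times):
                resid = stage.qts[k] - genetic[si][k] - g2 * (a_mat[rows] + t * b_mat[rows])
                total += float((resid ** 2).sum())
        return total

    B_old = B.copy()
    A_new = (S0 - g2 * B_old * tsum[:, None]) / (g2 * cnt[:, None])
    if record is not None:
        record.append(("A", fd_max_grad(lambda a: _aging_data_term(a, B_old), A_new.copy())))
    st["A"] = A = A_new
    B_new = B_old.copy()
    movable = t2sum > 0
    B_new[movable] = (S1[movable] - g2 * A[movable] * tsum[movable, None]) / (
        g2 * t2sum[movable, None])
    if record is not None:
        free = B_new.copy()

        def _b_term(bfree):
            full = B_old.copy()
            full[movable] = bfree[movable]
            return _aging_data_term(A, full)

        record.append(("B", fd_max_grad(_b_term, free)))
    st["B"] = B = B_new

    # ---- per-stage genetic blocks -----------------------------------------
    for si, stage in enumerate(data.stages):
        X = stage.genotype
        rows = data.registry_rows(stage)
        G = X.T @ X
        m = stage.n_visits
        T = float(stage.times.sum())
        T2 = float((stage.times ** 2).sum())
        XtZ0 = sum(X.T @ stage.qts[k] for k in range(m))
        XtZ1 = sum(t * (X.T @ stage.qts[k]) for k, t in enumerate(stage.times))
        XtA = X.T @ A[rows]
        XtB = X.T @ B[rows]
        aging = [g2 * (A[rows] + t * B[rows]) for t in stage.times]

        if use_gwas and config.tau > 0:
            scale = config.tau * (summary.n_ref - 1)
            if identity_weights:
                dpu = dqu = np.ones(d)
            else:
                dpu = row_weight(_stack(u[si], W[si]), delta, penalty)
                dqu = row_weight(_stack(u[si], V[si]), delta, penalty)
            m_u = summary.sigma + np.diag((lam_p[si] * dpu + lam_q[si] * dqu) / scale)
            if config.ridge > 0:
                m_u = m_u + config.ridge * np.eye(d)
            u[si] = np.linalg.solve(m_u, summary.beta)
            if record is not None:
                def _u_obj(uv):
                    return scale * float(uv @ summary.sigma @ uv
                                         - 2.0 * uv @ summary.beta
                                         + config.ridge * uv @ uv) + float(
                        ((lam_p[si] * dpu + lam_q[si] * dqu) * uv ** 2).sum())

                record.append((f"u[{si}]", fd_max_grad(_u_obj, u[si].copy())))

        us = u[si] if use_gwas else None

        dp = np.ones(d) if identity_weights else row_weight(_stack(us, W[si]), delta, penalty)
        rhs_w = g1 * (XtZ0 - g1 * T * (G @ V[si]) - g2 * (m * XtA + T * XtB))
        W[si] = np.linalg.solve(g1 * g1 * m * G + np.diag(lam_p[si] * dp), rhs_w)
        if record is not None:
            def _w_obj(wmat):
                xw = X @ wmat
                xv = X @ V[si]
                total = sum(
                    float(((stage.qts[k] - g1 * (xw + t * xv) - aging[k]) ** 2).sum())
                    for k, t in enumerate(stage.times))
                return total + lam_p[si] * float((dp * (wmat ** 2).sum(axis=1)).sum())

            record.append((f"W[{si}]", fd_max_grad(_w_obj, W[si].copy())))

        dq = np.ones(d) if identity_weights else row_weight(_stack(us, V[si]), delta, penalty)
        rhs_v = g1 * (XtZ1 - g1 * T * (G @ W[si]) - g2 * (T * XtA + T2 * XtB))
        V[si] = np.linalg.solve(g1 * g1 * T2 * G + np.diag(lam_q[si] * dq), rhs_v)
        if record is not None:
            def _v_obj(vmat):
                xw = X @ W[si]
                xv = X @ vmat
                total = sum(
                    float(((stage.qts[k] - g1 * (xw + t * xv) - aging[k]) ** 2).sum())
                    for k, t in enumerate(stage.times))
                return total + lam_q[si] * float((dq * (vmat ** 2).sum(axis=1)).sum())

            record.append((f"V[{si}]", fd_max_grad(_v_obj, V[si].copy())))


def reference_fit(data, summary, config, n_sweeps: int, *, penalty: str = "linf",
                  use_gwas: bool = True) -> tuple[dict, list[float]]:
    """Run the warm start (if configured) plus ``n_sweeps`` reweighted sweeps.

    Returns the final state and the surrogate objective logged before the
    first reweighted sweep and after each sweep, mirroring the engine trace.
    """
    st = init_state(data, use_gwas and summary is not None)
    if config.init_scheme == "warm":
        reference_sweep(data, summary, config, st, identity_weights=True, penalty=penalty)
    trace = [reference_objective(data, summary, config, st, penalty)[0]]
    for _ in range(n_sweeps):
        reference_sweep(data, summary, config, st, penalty=penalty)
        trace.append(reference_objective(data, summary, config, st, penalty)[0])
    return st, trace
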