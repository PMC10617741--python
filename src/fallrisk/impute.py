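"""Probabilistic PCA imputation of missing cells by expectation-maximization.

The model is x = W z + mu + eps with z ~ N(0, I_q) and isotropic noise
eps ~ N(0, sigma^2 I).  Columns are standardized before fitting (the domains
mix heterogeneous units) and de-standardized after.  Missing entries are
handled exactly in the E-step: for each row only the observed coordinates
inform the latent posterior, and missing cells are replaced by their
conditional expectations under the fitted model.  The observed-data
log-likelihood is tracked per iteration and is guaranteed non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import FeatureTable


@dataclass
class PpcaModel:
    W: np.ndarray  # p x q loading matrix (standardized scale)
    sigma2: float
    col_means: np.ndarray  # de-standardization parameters
    col_sds: np.ndarray
    q: int
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    names: list[str]


def _observed_loglik(xs: np.ndarray, mask: np.ndarray, w: np.ndarray, s2: float) -> float:
    """Sum over rows of log N(x_obs; 0, W_o W_o' + s2 I)."""
    total = 0.0
    for i in range(xs.shape[0]):
        o = ~mask[i]
        d = int(o.sum())
        wo = w[o]
        xo = xs[i, o]
        cov = wo @ wo.T + s2 * np.eye(d)
        sign, logdet = np.linalg.slogdet(cov)
        total += -0.5 * (d * np.log(2 * np.pi) + logdet + xo @ np.linalg.solve(cov, xo))
    return float(total)


def fit_ppca_em(
    t: FeatureTable,
    q: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = None,
) -> PpcaModel:
    """Fit PPCA to a table with missing cells by EM.

    Convergence is declared when the relative observed-data log-likelihood
    change falls below ``tol``; non-convergence at ``max_iter`` is reported
    in the returned model, not silenced.  The mean is fixed by column
    standardization over observed entries.
    """
    n, p = t.values.shape
    if q < 1 or q >= min(n, p):
        raise ValueError(f"latent dimension q={q} must satisfy 1 <= q < min(n, p)")
    mask = t.mask
    if mask.all(axis=1).any():
        raise ValueError("a row has no observed cells")
    if mask.all(axis=0).any():
        raise ValueError("a column has no observed cells")

    # standardize over observed entries
    col_means = np.empty(p)
    col_sds = np.empty(p)
    xs = t.values.copy()
    for j in range(p):
        obs = xs[~mask[:, j], j]
        col_means[j] = obs.mean()
        sd = obs.std(ddof=1)
        col_sds[j] = sd if sd > 0 else 1.0
        xs[:, j] = (xs[:, j] - col_means[j]) / col_sds[j]
    xs[mask] = 0.0  # placeholder; masked cells never enter the E-step

    rng = np.random.default_rng(seed)
    w = rng.standard_normal((p, q)) * 0.1
    s2 = 1.0
    eye_q = np.eye(q)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: per-row latent posterior from observed coordinates
        A = np.zeros((p, q))  # sum_i E[x_i z_i'];  rows: observed use data,
        B = np.zeros((q, q))  # sum_i E[z_i z_i']   missing use W_m E[zz']
        ex2_sum = 0.0  # sum_i E[||x_i||^2]
        ez_list = np.empty((n, q))
        for i in range(n):
            o = ~mask[i]
            wo = w[o]
            m_inv = np.linalg.inv(s2 * eye_q + wo.T @ wo)
            ez = m_inv @ wo.T @ xs[i, o]
            czz = s2 * m_inv + np.outer(ez, ez)
            ez_list[i] = ez
            B += czz
            A[o] += np.outer(xs[i, o], ez)
            miss = ~o
            if miss.any():
                wm = w[miss]
                A[miss] += wm @ czz
                # E[x_m^2] = diag(W_m Czz W_m') + s2
                ex2_sum += float(np.einsum("ij,jk,ik->", wm, czz, wm)) + s2 * int(miss.sum())
            ex2_sum += float(xs[i, o] @ xs[i, o])
        # M-step
        w_new = A @ np.linalg.inv(B)
        s2_new = (
            ex2_sum - 2.0 * float(np.sum(w_new * A)) + float(np.einsum("ij,jk,ik->", w_new, B, w_new))
        ) / (n * p)
        s2_new = max(s2_new, 1e-12)
        w, s2 = w_new, s2_new

        ll = _observed_loglik(xs, mask, w, s2)
        trace.append(ll)
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1e-12)
            if (trace[-1] - trace[-2]) / denom < tol and trace[-1] >= trace[-2] - 1e-8:
                converged = True
                break

    return PpcaModel(
        W=w,
        sigma2=float(s2),
        col_means=col_means,
        col_sds=col_sds,
        q=q,
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
        names=t.names,
    )


def impute_missing(t: FeatureTable, model: PpcaModel) -> FeatureTable:
    """Replace missing cells with conditional expectations under the model.

    Observed cells are bitwise untouched; the returned table has an all-False
    mask.  A table with no missing cells is returned as a copy unchanged.
    """
    if model.names != t.names:
        raise ValueError("model columns do not match the table")
    vals = t.values.copy()
    if not t.mask.any():
        return replace(t, values=vals, mask=np.zeros_like(t.mask))
    eye_q = np.eye(model.q)
    for i in range(t.n):
        miss = t.mask[i]
        if not miss.any():
            continue
        o = ~miss
        xo = (t.values[i, o] - model.col_means[o]) / model.col_sds[o]
        wo = model.W[o]
        m_inv = np.linalg.inv(model.sigma2 * eye_q + wo.T @ wo)
        ez = m_inv @ wo.T @ xo
        xm = model.W[miss] @ ez
        vals[i, miss] = xm * model.col_sds[miss] + model.col_means[miss]
    return replace(t, values=vals, mask=np.zeros_like(t.mask))


def ppca_impute(
    t: FeatureTable, q: int = 5, tol: float = 1e-6, max_iter: int = 1000, seed: int | None = None
) -> tuple[FeatureTable, PpcaModel]:
    """Convenience wrapper: fit the PPCA model and impute in one call."""
    if not t.mask.any():
        model = fit_ppca_em(t, q=q, tol=tol, max_iter=2, seed=seed)
        return impute_missing(t, model), model
    model = fit_ppca_em(t, q=q, tol=tol, max_iter=max_iter, seed=seed)
    return impute_missing(t, model), model
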