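"""Partial least squares correlation analysis (PLSCA).

PLSCA decomposes the cross-correlation matrix R = X'Y/(n-1) of two z-scored
data blocks by SVD.  The singular-value inertia (sum of squared singular
values over the retained components) quantifies the shared information
between the blocks; untruncated it equals the squared Frobenius norm of R.
Variable importance is measured leave-one-variable-out (LOVO): a variable's
importance is the decrease in inertia when it is excluded and the
decomposition refitted.  For discriminating fallers from non-fallers the X
block is the single z-scored faller indicator column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import FeatureTable, zscore_columns

_ZTOL = 1e-6


def _as_block(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _check_standardized(a: np.ndarray, label: str) -> None:
    if np.isnan(a).any():
        raise ValueError(f"{label} block contains missing values; impute first")
    mu = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    if np.max(np.abs(mu)) > 1e-6 or np.max(np.abs(sd - 1)) > 1e-6:
        raise ValueError(
            f"{label} block is not z-scored (column means/SDs deviate from 0/1)"
        )


def zscore_vector(v) -> np.ndarray:
    """z-score a 1-D vector (e.g. the 0/1 faller indicator) with sample SD."""
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be z-scored")
    return (v - v.mean()) / sd


def cross_correlation(x, y) -> np.ndarray:
    """Cross-correlation matrix R = X'Y/(n-1) of two z-scored blocks.

    Entries are the pairwise Pearson correlations between X columns and Y
    columns.  Both blocks must already be z-scored over the same rows.
    """
    xb, yb = _as_block(x), _as_block(y)
    if xb.shape[0] != yb.shape[0]:
        raise ValueError("blocks have different numbers of rows")
    _check_standardized(xb, "x")
    _check_standardized(yb, "y")
    return xb.T @ yb / (xb.shape[0] - 1)


@dataclass
class PlscaResult:
    """SVD decomposition of a cross-block correlation matrix."""

    singular_values: np.ndarray  # non-increasing
    left_saliences: np.ndarray  # columns orthonormal (U)
    right_saliences: np.ndarray  # columns orthonormal (V)
    inertia: float  # sum of squared retained singular values
    k: int  # retained components

    @property
    def all_inertia(self) -> float:
        return float(np.sum(self.singular_values**2))


def fit_plsca(x, y, k: int | None = None) -> PlscaResult:
    """SVD of the cross-correlation matrix of two z-scored blocks.

    ``k`` limits the retained components for the inertia; the default keeps
    all, for which the inertia equals ||R||_F^2.
    """
    r = cross_correlation(x, y)
    if np.allclose(r, 0.0):
        raise ValueError("degenerate all-zero cross-correlation matrix")
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    k_eff = len(s) if k is None else min(k, len(s))
    return PlscaResult(
        singular_values=s,
        left_saliences=u,
        right_saliences=vt.T,
        inertia=float(np.sum(s[:k_eff] ** 2)),
        k=k_eff,
    )


def plsca_from_r(r: np.ndarray, k: int | None = None) -> PlscaResult:
    """Fit directly from a precomputed cross-correlation matrix."""
    r = np.atleast_2d(np.asarray(r, dtype=float))
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    k_eff = len(s) if k is None else min(k, len(s))
    return PlscaResult(s, u, vt.T, float(np.sum(s[:k_eff] ** 2)), k_eff)


@dataclass
class LovoImportance:
    """Per-variable decrease in inertia when that variable is left out."""

    names: list[str]
    importance: np.ndarray
    baseline_inertia: float


def lovo_importance(x, y, names: list[str] | None = None, k: int | None = None) -> LovoImportance:
    """Leave-one-variable-out importance over the columns of the y block.

    For each column j the PLSCA is refitted on y without column j;
    importance_j = full inertia - inertia without j.  With untruncated
    inertia this equals the squared norm of R's dropped column, so every
    importance is non-negative and they sum to the baseline when x has one
    column.
    """
    yb = _as_block(y)
    if yb.shape[1] < 2:
        raise ValueError("LOVO needs at least 2 variables in the y block")
    if names is None:
        names = [f"v{j + 1}" for j in range(yb.shape[1])]
    full = fit_plsca(x, yb, k=k)
    imp = np.empty(yb.shape[1])
    for j in range(yb.shape[1]):
        reduced = fit_plsca(x, np.delete(yb, j, axis=1), k=k)
        imp[j] = full.inertia - reduced.inertia
    return LovoImportance(list(names), imp, full.inertia)


def between_domain_inertia(a: FeatureTable, b: FeatureTable, k: int | None = None):
    """Measured and normalized shared information between two domain blocks.

    Measured inertia comes from the PLSCA of the two z-scored blocks;
    normalized inertia divides by the total variable count p_a + p_b so that
    domain pairs of different sizes are comparable.
    """
    if a.p == 0 or b.p == 0:
        raise ValueError("empty domain block")
    za, zb = zscore_columns(a), zscore_columns(b)
    res = fit_plsca(za.values, zb.values, k=k)
    return res.inertia, normalize_inertia(res.inertia, a.p, b.p)


def normalize_inertia(measured: float, p_a: int, p_b: int) -> float:
    """Normalized inertia: measured inertia / (p_a + p_b)."""
    if p_a <= 0 or p_b <= 0:
        raise ValueError("variable counts must be positive")
    return measured / (p_a + p_b)


def permutation_pvalue(
    x, y, b: int = 999, seed: int | None = None, k: int | None = None
) -> float:
    """Permutation p-value for the observed inertia between two blocks.

    Rows of y are permuted b times; p = (1 + #{perm >= observed}) / (b + 1).
    """
    if b < 99:
        raise ValueError("use at least 99 permutations")
    xb, yb = _as_block(x), _as_block(y)
    observed = fit_plsca(xb, yb, k=k).inertia
    rng = np.random.default_rng(seed)
    count = 0
    n = yb.shape[0]
    for _ in range(b):
        perm = rng.permutation(n)
        # permuted columns keep mean 0 / SD 1, so refit directly on rows
        r = xb.T @ yb[perm] / (n - 1)
        s = np.linalg.svd(r, compute_uv=False)
        k_eff = len(s) if k is None else min(k, len(s))
        if float(np.sum(s[:k_eff] ** 2)) >= observed - 1e-12:
            count += 1
    return (1 + count) / (b + 1)


def latent_scores(res: PlscaResult, y, orient=None) -> np.ndarray:
    """Participant projections on the first right salience.

    SVD sign ambiguity is resolved by orienting the first salience so that
    the scores correlate positively with ``orient`` (e.g. the faller coding)
    when given, otherwise so that the salience's largest-magnitude entry is
    positive.
    """
    yb = _as_block(y)
    v1 = res.right_saliences[:, 0]
    if v1.shape[0] != yb.shape[1]:
        raise ValueError("result does not match the y block's columns")
    scores = yb @ v1
    if orient is not None:
        orient = np.asarray(orient, dtype=float)
        if np.corrcoef(scores, orient)[0, 1] < 0:
            scores = -scores
    elif v1[np.argmax(np.abs(v1))] < 0:
        scores = -scores
    return scores
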