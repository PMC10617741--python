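"""Univariate screening statistics for two-group comparisons.

Welch two-sample t-tests with pooled-SD Cohen's d for continuous variables,
Yates-corrected chi-square with Cramer's V for 2x2 categorical tables,
pairwise-complete Pearson correlation matrices with collinearity flags, and
Bartlett's test of sphericity for overall redundancy.  Effect sizes are
reported as magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FeatureTable


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of a continuous variable in the two groups."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 observations per group")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class UnivariateResult:
    statistic: float
    df: float
    p_value: float
    effect_size: float
    effect_family: str  # "cohens_d" | "cramers_v"


def welch_t(gs: GroupSummary) -> UnivariateResult:
    """Welch unequal-variance t-test from group summaries (two-tailed).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite df.
    """
    if gs.sd1 == 0 and gs.sd2 == 0:
        raise ValueError("both group SDs are zero")
    res = stats.ttest_ind_from_stats(
        gs.mean1, gs.sd1, gs.n1, gs.mean2, gs.sd2, gs.n2, equal_var=False
    )
    v1, v2 = gs.sd1**2 / gs.n1, gs.sd2**2 / gs.n2
    df = (v1 + v2) ** 2 / (v1**2 / (gs.n1 - 1) + v2**2 / (gs.n2 - 1))
    return UnivariateResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        effect_size=cohens_d(gs),
        effect_family="cohens_d",
    )


def cohens_d(gs: GroupSummary) -> float:
    """Pooled-SD Cohen's d magnitude: |m1 - m2| / s_pooled."""
    sp2 = ((gs.n1 - 1) * gs.sd1**2 + (gs.n2 - 1) * gs.sd2**2) / (gs.n1 + gs.n2 - 2)
    if sp2 == 0:
        raise ValueError("pooled SD is zero")
    return float(abs(gs.mean1 - gs.mean2) / np.sqrt(sp2))


def chi2_cramers_v(table2x2) -> UnivariateResult:
    """Yates continuity-corrected chi-square and Cramer's V on a 2x2 table.

    chi2 = n (|ad - bc| - n/2)^2 / (r1 r2 c1 c2), floored at 0 when
    |ad - bc| <= n/2 (the correction would otherwise overshoot);
    V = sqrt(chi2 / n) for a 2x2 table.
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    n = t.sum()
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin in the 2x2 table")
    a, b = t[0]
    c, d = t[1]
    cross = abs(a * d - b * c)
    chi2 = 0.0 if cross <= n / 2 else n * (cross - n / 2) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    v = float(np.sqrt(chi2 / n))
    return UnivariateResult(chi2, 1.0, p, v, "cramers_v")


# correlation-magnitude interpretation thresholds
R_SMALL, R_MODERATE, R_LARGE = 0.10, 0.30, 0.50


def r_label(r: float) -> str:
    a = abs(r)
    if a >= R_LARGE:
        return "large"
    if a >= R_MODERATE:
        return "moderate"
    if a >= R_SMALL:
        return "small"
    return "negligible"


def pearson_matrix(t: FeatureTable, min_pairs: int = 3):
    """Pairwise-complete Pearson correlations with p-values and flags.

    Returns (r, p, flags): r is a symmetric unit-diagonal DataFrame, p the
    two-sided p-values from the t transform on the pairwise-complete n, and
    flags a long-format frame with magnitude labels and the |r| > 0.50
    collinearity flag.
    """
    names = t.names
    p_count = t.p
    r = np.eye(p_count)
    pv = np.zeros((p_count, p_count))
    rows = []
    for i in range(p_count):
        for j in range(i + 1, p_count):
            ok = ~(t.mask[:, i] | t.mask[:, j])
            n_ij = int(ok.sum())
            if n_ij < min_pairs:
                raise ValueError(
                    f"fewer than {min_pairs} complete pairs for "
                    f"({names[i]!r}, {names[j]!r})"
                )
            rij, pij = stats.pearsonr(t.values[ok, i], t.values[ok, j])
            r[i, j] = r[j, i] = rij
            pv[i, j] = pv[j, i] = pij
            rows.append(
                {
                    "var_a": names[i],
                    "var_b": names[j],
                    "r": rij,
                    "p": pij,
                    "n": n_ij,
                    "magnitude": r_label(rij),
                    "collinear": abs(rij) > R_LARGE,
                }
            )
    return (
        pd.DataFrame(r, index=names, columns=names),
        pd.DataFrame(pv, index=names, columns=names),
        pd.DataFrame(rows),
    )


def bartlett_sphericity(r, n: int) -> UnivariateResult:
    """Bartlett's test that a correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) ln det(R) on p(p-1)/2 df; a small p-value
    indicates redundancy (correlated, non-orthogonal variables).
    """
    rm = np.asarray(r, dtype=float)
    p = rm.shape[0]
    if n <= p:
        raise ValueError("Bartlett's sphericity requires n > p")
    sign, logdet = np.linalg.slogdet(rm)
    if sign <= 0:
        raise ValueError("correlation matrix is singular or not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return UnivariateResult(float(chi2), df, float(stats.chi2.sf(chi2, df)), float("nan"), "none")


def significance_flag(p: float) -> str:
    """Table-footnote style flags: * p<=0.10, ** p<=0.05, *** p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.10:
        return "*"
    return ""


def screen_table(t: FeatureTable) -> pd.DataFrame:
    """Univariate screen of every variable in a table (TSV-ready frame).

    Continuous variables get the Welch test and Cohen's d from the observed
    per-group values; binary variables get the Yates chi-square and
    Cramer's V from the 2x2 group-by-event counts.
    """
    y = t.y
    rows = []
    for j, v in enumerate(t.variables):
        obs = ~t.mask[:, j]
        x1 = t.values[obs & (y == 1), j]
        x2 = t.values[obs & (y == 0), j]
        if v.kind == "continuous":
            gs = GroupSummary(
                len(x1), float(x1.mean()), float(x1.std(ddof=1)),
                len(x2), float(x2.mean()), float(x2.std(ddof=1)),
            )
            res = welch_t(gs)
        else:
            tab = [
                [float((x1 == 1).sum()), float((x1 == 0).sum())],
                [float((x2 == 1).sum()), float((x2 == 0).sum())],
            ]
            res = chi2_cramers_v(tab)
        rows.append(
            {
                "variable": v.name,
                "domain": v.domain,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "effect_size": res.effect_size,
                "effect_family": res.effect_family,
                "flag": significance_flag(res.p_value),
            }
        )
    return pd.DataFrame(rows)
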