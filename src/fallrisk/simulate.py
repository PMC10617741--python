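"""Synthetic faller / non-faller cohort generator.

No raw data from the study cohort are available, so every downstream stage is
exercised on simulated cohorts that reproduce the study's statistical
structure: 21 fallers vs 39 non-fallers, per-variable two-group means/SDs
taken from the published summary tables, block multicollinearity (strong
within-domain correlation, a strongly coupled strength / body-composition
pair, weakly coupled balance variables), optional nuisance variables with no
group effect, MCAR missingness, and trial-level gait series for the
derived-feature formulas.

Continuous variables are drawn from a multivariate normal per group with the
group's mean vector and an SD-scaled covariance assembled from correlation
blocks; binary variables are generated by thresholding latent normals at the
group's event-probability quantile (a Gaussian-copula construction, since
only marginals are published).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import DOMAINS, FALLER, NON_FALLER, FeatureTable, VariableSpec
from . import tables


@dataclass
class VariableModel:
    """Generative spec for one variable: group means/SDs or event probs."""

    name: str
    domain: str
    kind: str = "continuous"
    faller_mean: float = 0.0
    faller_sd: float = 1.0
    nonfaller_mean: float = 0.0
    nonfaller_sd: float = 1.0
    faller_prob: float = 0.5  # binary variables only
    nonfaller_prob: float = 0.5
    source: str = "multi_domain"

    def __post_init__(self) -> None:
        if self.kind == "continuous" and (self.faller_sd <= 0 or self.nonfaller_sd <= 0):
            raise ValueError(f"{self.name!r}: SDs must be positive")
        for p in (self.faller_prob, self.nonfaller_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name!r}: probabilities must be in [0, 1]")

    @property
    def spec(self) -> VariableSpec:
        return VariableSpec(name=self.name, domain=self.domain, kind=self.kind)


@dataclass
class CorrelationStructure:
    """Within-domain and cross-domain correlation levels on latent normals.

    Defaults emulate the published dependence pattern: substantial
    within-domain multicollinearity, a strongly shared strength /
    body-composition pair, balance only weakly coupled to everything else,
    and moderate coupling among the remaining domain pairs.
    """

    within: dict[str, float] = field(
        default_factory=lambda: {d: 0.6 for d in DOMAINS}
    )
    cross: dict[frozenset, float] = field(
        default_factory=lambda: {
            frozenset(("strength", "body_composition")): 0.7,
        }
    )
    default_cross: float = 0.3
    balance_cross: float = 0.1

    def pair_r(self, dom_a: str, dom_b: str) -> float:
        if dom_a == dom_b:
            return self.within.get(dom_a, 0.0)
        key = frozenset((dom_a, dom_b))
        if key in self.cross:
            return self.cross[key]
        if "balance" in key:
            return self.balance_cross
        return self.default_cross


@dataclass
class CohortConfig:
    """Full generative specification of a synthetic cohort."""

    variables: list[VariableModel]
    n_fallers: int = 21
    n_nonfallers: int = 39
    correlation: CorrelationStructure = field(default_factory=CorrelationStructure)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fallers < 2 or self.n_nonfallers < 2:
            raise ValueError("need at least 2 participants per group")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in config")

    @property
    def p(self) -> int:
        return len(self.variables)

    def subset(self, source: str) -> "CohortConfig":
        """Config restricted to variables from one source table group."""
        return CohortConfig(
            variables=[v for v in self.variables if v.source == source],
            n_fallers=self.n_fallers,
            n_nonfallers=self.n_nonfallers,
            correlation=self.correlation,
            missing_rate=self.missing_rate,
            seed=self.seed,
        )


def builtin_fixture_config(
    n_nuisance: int = 0,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> CohortConfig:
    """Config encoding every published variable with its printed group stats.

    The 51 multi-domain variables (11 balance, 11 gait, 5 clinical, 14
    strength, 10 body composition) plus the baseline descriptives, with the
    default correlation structure.  ``n_nuisance`` appends that many
    no-group-effect variables per domain (emulating the redundant remainder
    of the full variable battery) so selection stages have chaff to discard.
    """
    variables = [
        VariableModel(nm, dom, "continuous", fm, fs, nm2, ns2, source="multi_domain")
        for nm, dom, fm, fs, nm2, ns2 in tables.MULTI_DOMAIN
    ]
    variables += [
        VariableModel(nm, dom, "continuous", fm, fs, nm2, ns2, source="descriptives")
        for nm, dom, fm, fs, nm2, ns2 in tables.DESCRIPTIVES
    ]
    variables += [
        VariableModel(
            nm, dom, "binary",
            faller_prob=k1 / n1, nonfaller_prob=k2 / n2,
            source="descriptives",
        )
        for nm, dom, k1, n1, k2, n2 in tables.BINARY_DESCRIPTIVES
    ]
    if n_nuisance:
        for dom in DOMAINS:
            for i in range(n_nuisance):
                variables.append(
                    VariableModel(
                        f"nuisance {dom} {i + 1}", dom, "continuous",
                        10.0, 2.0, 10.0, 2.0, source="nuisance",
                    )
                )
    return CohortConfig(variables=variables, missing_rate=missing_rate, seed=seed)


def assemble_correlation(cfg: CohortConfig) -> tuple[np.ndarray, float]:
    """Build the latent correlation matrix and repair it to nearest PSD.

    Block-constant targets (within-domain r on the diagonal blocks, pairwise
    cross-domain r off the blocks) are generally not positive semi-definite;
    negative eigenvalues are clipped to a small positive floor and the matrix
    rescaled back to unit diagonal.  Returns (matrix, largest absolute
    adjustment applied to any entry).
    """
    p = cfg.p
    corr = np.empty((p, p))
    doms = [v.domain for v in cfg.variables]
    for i in range(p):
        for j in range(p):
            corr[i, j] = 1.0 if i == j else cfg.correlation.pair_r(doms[i], doms[j])
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-8:
        w_clipped = np.clip(w, 1e-8, None)
        repaired = (v * w_clipped) @ v.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        np.fill_diagonal(repaired, 1.0)
        adjustment = float(np.max(np.abs(repaired - corr)))
        corr = repaired
    else:
        adjustment = 0.0
    return corr, adjustment


def generate_cohort(cfg: CohortConfig, seed: int | None = None) -> FeatureTable:
    """Draw a synthetic cohort table; fully reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    corr, adjustment = assemble_correlation(cfg)
    if adjustment > 0.35:
        raise ValueError(
            f"correlation repair moved an entry by {adjustment:.3f}; "
            "the requested block structure is too far from PSD"
        )
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(cfg.p))

    rows, ids, groups = [], [], []
    for label, n in ((FALLER, cfg.n_fallers), (NON_FALLER, cfg.n_nonfallers)):
        z = rng.standard_normal((n, cfg.p)) @ chol.T
        x = np.empty_like(z)
        for j, v in enumerate(cfg.variables):
            if v.kind == "continuous":
                mu = v.faller_mean if label == FALLER else v.nonfaller_mean
                sd = v.faller_sd if label == FALLER else v.nonfaller_sd
                x[:, j] = mu + sd * z[:, j]
            else:
                prob = v.faller_prob if label == FALLER else v.nonfaller_prob
                x[:, j] = (z[:, j] > norm.ppf(1.0 - prob)).astype(float)
        rows.append(x)
        ids += [f"{'F' if label == FALLER else 'N'}{i + 1:03d}" for i in range(n)]
        groups += [label] * n
    values = np.vstack(rows)
    mask = rng.random(values.shape) < cfg.missing_rate
    values = values.copy()
    values[mask] = np.nan
    return FeatureTable(ids, groups, [v.spec for v in cfg.variables], values, mask)


def generate_trial_level(
    cfg: CohortConfig,
    steps: int = 5,
    dispersion: float = 0.05,
    relative: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-participant, per-gait-variable trial series (5 steps by default).

    Each participant's latent level is drawn from the variable's group
    distribution; the per-step values scatter about it with Laplace noise of
    scale ``dispersion`` (times |level| when ``relative``), so the expected
    MAD of a long series is b*ln(2) for scale b.  Returns a long-format
    frame (participant, variable, trial_index, value).
    """
    if steps < 2:
        raise ValueError("need at least 2 steps per trial series")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gait_vars = [v for v in cfg.variables if v.domain == "gait" and v.kind == "continuous"]
    records = []
    pid = 0
    for label, n in ((FALLER, cfg.n_fallers), (NON_FALLER, cfg.n_nonfallers)):
        for _ in range(n):
            pid += 1
            pname = f"P{pid:03d}"
            for v in gait_vars:
                mu = v.faller_mean if label == FALLER else v.nonfaller_mean
                sd = v.faller_sd if label == FALLER else v.nonfaller_sd
                level = rng.normal(mu, sd)
                b = dispersion * abs(level) if relative else dispersion
                vals = level + rng.laplace(0.0, b, size=steps) if b > 0 else np.full(steps, level)
                for k in range(steps):
                    records.append((pname, label, v.name, k + 1, vals[k]))
    return pd.DataFrame(
        records, columns=["participant", "group", "variable", "trial_index", "value"]
    )
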