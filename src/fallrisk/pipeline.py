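"""Two-stage analysis orchestration: single-domain screens, then the
multi-domain refinement.

Stage 1 runs each domain "data package" through the univariate screen, both
importance engines (random-forest Gini and LOVO PLSCA), Jenks elbow
selection and set union, and classifier evaluation; the union is the
domain's "important" variable list.  Stage 2 aggregates the important
variables across domains, PPCA-imputes missing cells, repeats the screen /
importance / selection / union sequence, fits the three classifiers with
ROC and LOOCV, refines the logistic model backward by AIC and by BIC
(reporting whether they agree), and tabulates pairwise between-domain
shared information (measured inertia, normalized inertia, permutation p).

Every stochastic stage draws its seed from the run configuration, so the
whole pipeline is a pure function of (input table, RunConfig).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import FeatureTable, partition_domains, zscore_columns
from .classify import (
    logistic_fit,
    loocv_accuracy,
    plsca_classifier,
    rf_classifier,
    stepwise_backward,
)
from .forest import fit_forest
from .impute import ppca_impute
from .plsca import (
    fit_plsca,
    lovo_importance,
    normalize_inertia,
    permutation_pvalue,
    zscore_vector,
)
from .selection import select_above_break, union_important
from .univariate import screen_table


@dataclass
class RunConfig:
    """Engine parameters and seeds for a pipeline run."""

    n_trees: int = 500
    ppca_q: int = 5
    permutations: int = 999
    seed: int = 0
    jenks_cutoff_rf: float | None = None  # manual overrides ("subjective validation")
    jenks_cutoff_lovo: float | None = None
    max_logistic_predictors: int | None = None

    def stage_seed(self, offset: int) -> int:
        return (self.seed * 1000 + offset) % (2**31 - 1)


@dataclass
class DomainReport:
    domain: str
    screen: pd.DataFrame
    rf_selection: object
    lovo_selection: object
    important: list[str]
    provenance: dict[str, str]
    rf_importance: pd.DataFrame
    lovo_importance_table: pd.DataFrame
    classifiers: dict
    oob_error: float
    oob_p_value: float


def _importance_stage(t: FeatureTable, cfg: RunConfig, offset: int):
    """Shared RF + LOVO importance and Jenks-union selection."""
    forest = fit_forest(t, n_trees=cfg.n_trees, seed=cfg.stage_seed(offset))
    rf_sel = select_above_break(
        forest.names, forest.importance, engine="rf", cutoff=cfg.jenks_cutoff_rf
    )
    z = zscore_columns(t)
    lovo = lovo_importance(zscore_vector(t.y), z.values, names=t.names)
    lovo_sel = select_above_break(
        lovo.names, lovo.importance, engine="lovo", cutoff=cfg.jenks_cutoff_lovo
    )
    important, provenance = union_important(rf_sel, lovo_sel)
    rf_table = pd.DataFrame(
        {"variable": forest.names, "mean_decrease_gini": forest.importance}
    ).sort_values("mean_decrease_gini", ascending=False, ignore_index=True)
    rf_table["rank"] = np.arange(1, len(rf_table) + 1)
    lovo_table = pd.DataFrame(
        {"variable": lovo.names, "inertia_decrease": lovo.importance}
    ).sort_values("inertia_decrease", ascending=False, ignore_index=True)
    lovo_table["rank"] = np.arange(1, len(lovo_table) + 1)
    return forest, rf_sel, lovo_sel, important, provenance, rf_table, lovo_table


def _classifier_suite(t: FeatureTable, predictors: list[str], cfg: RunConfig, offset: int) -> dict:
    """PLSCA, random-forest and (when feasible) logistic ROC evaluation."""
    out: dict = {}
    out["plsca"] = plsca_classifier(t, predictors)
    out["rf"] = rf_classifier(t, predictors, n_trees=cfg.n_trees, seed=cfg.stage_seed(offset))
    cap = cfg.max_logistic_predictors
    feasible = len(predictors) < t.n - 1 and (cap is None or len(predictors) <= cap)
    if feasible:
        try:
            logit = logistic_fit(t, predictors)
            from .classify import roc_auc

            out["logistic"] = roc_auc(logit.fitted_probabilities, t.y)
            out["logistic_report"] = logit
        except Exception as exc:  # singular / separated designs at small n
            out["logistic_error"] = str(exc)
    else:
        out["logistic_error"] = "skipped: too many predictors for n"
    return out


def run_single_domain(domain_table: FeatureTable, cfg: RunConfig, offset: int = 0) -> DomainReport:
    """Stage-1 analysis of one domain data package.

    Missing cells are PPCA-imputed first (the multivariate engines need a
    complete matrix), then: univariate screen, RF + LOVO importance, Jenks
    selections, union, and baseline + refined classifier evaluation.
    """
    dom = domain_table.variables[0].domain
    if domain_table.mask.any():
        t, _ = ppca_impute(
            domain_table,
            q=min(cfg.ppca_q, domain_table.p - 1, domain_table.n - 1),
            seed=cfg.stage_seed(offset + 1),
        )
    else:
        t = domain_table
    screen = screen_table(t)
    forest, rf_sel, lovo_sel, important, provenance, rf_table, lovo_table = _importance_stage(
        t, cfg, offset + 2
    )
    classifiers = {"baseline": _classifier_suite(t, t.names, cfg, offset + 3)}
    if important:
        classifiers["refined"] = _classifier_suite(t, important, cfg, offset + 4)
    return DomainReport(
        domain=dom,
        screen=screen,
        rf_selection=rf_sel,
        lovo_selection=lovo_sel,
        important=important,
        provenance=provenance,
        rf_importance=rf_table,
        lovo_importance_table=lovo_table,
        classifiers=classifiers,
        oob_error=forest.oob_error,
        oob_p_value=forest.oob_p_value,
    )


@dataclass
class MultiDomainReport:
    important_by_domain: dict[str, list[str]]
    table: FeatureTable  # imputed multi-domain package
    screen: pd.DataFrame
    rf_selection: object
    lovo_selection: object
    refined: list[str]
    provenance: dict[str, str]
    rf_importance: pd.DataFrame
    lovo_importance_table: pd.DataFrame
    classifiers: dict
    loocv: dict
    stepwise_aic: object
    stepwise_bic: object
    stepwise_agree: bool
    inertia_table: pd.DataFrame


def run_multi_domain(
    partition: dict[str, FeatureTable],
    single_reports: dict[str, DomainReport],
    cfg: RunConfig,
) -> MultiDomainReport:
    """Stage-2 analysis on the variables the single-domain stages selected."""
    from .cohort import concat_columns

    important_by_domain = {d: r.important for d, r in single_reports.items()}
    blocks = [
        partition[d].subset(names)
        for d, names in important_by_domain.items()
        if names
    ]
    if not blocks:
        raise ValueError("no domain produced an important variable set")
    multi = concat_columns(blocks)
    if multi.mask.any():
        multi, _ = ppca_impute(
            multi, q=min(cfg.ppca_q, multi.p - 1, multi.n - 1), seed=cfg.stage_seed(100)
        )
    screen = screen_table(multi)
    forest, rf_sel, lovo_sel, refined, provenance, rf_table, lovo_table = _importance_stage(
        multi, cfg, 101
    )
    classifiers = {"baseline": _classifier_suite(multi, multi.names, cfg, 103)}
    loocv: dict = {}
    stepwise_aic = stepwise_bic = None
    stepwise_agree = False
    if refined:
        classifiers["refined"] = _classifier_suite(multi, refined, cfg, 104)
        if len(refined) < multi.n - 1:
            acc, bad = loocv_accuracy(multi, refined)
            loocv["refined_full"] = {"accuracy": acc, "non_convergent_folds": bad}
            stepwise_aic = stepwise_backward(multi, refined, "aic")
            stepwise_bic = stepwise_backward(multi, refined, "bic")
            stepwise_agree = set(stepwise_aic.predictors) == set(stepwise_bic.predictors)
            if stepwise_aic.predictors:
                acc2, bad2 = loocv_accuracy(multi, stepwise_aic.predictors)
                loocv["stepwise_aic"] = {"accuracy": acc2, "non_convergent_folds": bad2}
    inertia_table = between_domain_table(partition, cfg)
    return MultiDomainReport(
        important_by_domain=important_by_domain,
        table=multi,
        screen=screen,
        rf_selection=rf_sel,
        lovo_selection=lovo_sel,
        refined=refined,
        provenance=provenance,
        rf_importance=rf_table,
        lovo_importance_table=lovo_table,
        classifiers=classifiers,
        loocv=loocv,
        stepwise_aic=stepwise_aic,
        stepwise_bic=stepwise_bic,
        stepwise_agree=stepwise_agree,
        inertia_table=inertia_table,
    )


def between_domain_table(partition: dict[str, FeatureTable], cfg: RunConfig) -> pd.DataFrame:
    """Pairwise shared-information table across domains.

    Long-format rows (domain_a, domain_b, measured, normalized, p); the
    layout is symmetric with the diagonal not applicable.  Blocks are
    imputed per-domain if needed, z-scored, and compared by PLSCA inertia
    with a row-permutation p-value.
    """
    domains = list(partition)
    z_blocks: dict[str, np.ndarray] = {}
    for d in domains:
        t = partition[d]
        if t.mask.any():
            t, _ = ppca_impute(
                t, q=min(cfg.ppca_q, t.p - 1, t.n - 1), seed=cfg.stage_seed(200)
            )
        z_blocks[d] = zscore_columns(t).values
    rows = []
    for i, da in enumerate(domains):
        for db in domains[i + 1:]:
            res = fit_plsca(z_blocks[da], z_blocks[db])
            p = permutation_pvalue(
                z_blocks[da],
                z_blocks[db],
                b=cfg.permutations,
                seed=cfg.stage_seed(201 + i),
            )
            rows.append(
                {
                    "domain_a": da,
                    "domain_b": db,
                    "measured_inertia": res.inertia,
                    "normalized_inertia": normalize_inertia(
                        res.inertia, z_blocks[da].shape[1], z_blocks[db].shape[1]
                    ),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(table: FeatureTable, cfg: RunConfig):
    """Full two-stage pipeline on a tagged feature table."""
    partition = partition_domains(table)
    singles = {
        d: run_single_domain(t, cfg, offset=10 * (i + 1))
        for i, (d, t) in enumerate(partition.items())
    }
    multi = run_multi_domain(partition, singles, cfg)
    return singles, multi


# -- report writing ----------------------------------------------------------

def _roc_summary(rep) -> dict:
    return {
        "auc": round(rep.auc, 4),
        "auc_p_value": float(rep.auc_p_value),
        "cutoff": round(rep.cutoff, 4),
        "sensitivity": round(rep.sensitivity, 4),
        "specificity": round(rep.specificity, 4),
        "confusion": rep.confusion,
    }


def write_report(
    singles: dict[str, DomainReport],
    multi: MultiDomainReport,
    cfg: RunConfig,
    outdir: str | Path,
) -> list[Path]:
    """Write machine-readable TSV / YAML outputs plus a text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    for d, rep in singles.items():
        _tsv(rep.screen, f"screen_{d}.tsv")
        _tsv(rep.rf_importance, f"importance_rf_{d}.tsv")
        _tsv(rep.lovo_importance_table, f"importance_lovo_{d}.tsv")
    _tsv(multi.screen, "screen_multi_domain.tsv")
    _tsv(multi.rf_importance, "importance_rf_multi_domain.tsv")
    _tsv(multi.lovo_importance_table, "importance_lovo_multi_domain.tsv")
    _tsv(multi.inertia_table, "between_domain_inertia.tsv")

    summary = {
        "config": asdict(cfg),
        "domains": {
            d: {
                "n_variables": len(rep.screen),
                "n_important": len(rep.important),
                "important": rep.important,
                "oob_error": round(rep.oob_error, 4),
                "oob_p_value": round(rep.oob_p_value, 4),
                "classifiers": {
                    stage: {
                        name: _roc_summary(r)
                        for name, r in cls.items()
                        if hasattr(r, "auc")
                    }
                    for stage, cls in rep.classifiers.items()
                },
            }
            for d, rep in singles.items()
        },
        "multi_domain": {
            "n_variables": multi.table.p,
            "refined": multi.refined,
            "provenance": multi.provenance,
            "classifiers": {
                stage: {
                    name: _roc_summary(r) for name, r in cls.items() if hasattr(r, "auc")
                }
                for stage, cls in multi.classifiers.items()
            },
            "loocv": multi.loocv,
            "stepwise_agree": multi.stepwise_agree,
            "stepwise_aic_predictors": (
                multi.stepwise_aic.predictors if multi.stepwise_aic else None
            ),
            "stepwise_bic_predictors": (
                multi.stepwise_bic.predictors if multi.stepwise_bic else None
            ),
        },
    }
    ypath = outdir / "report.yaml"
    with open(ypath, "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False, default_flow_style=False)
    written.append(ypath)

    lines = ["Falls-risk discrimination pipeline summary", "=" * 44, ""]
    for d, rep in singles.items():
        lines.append(
            f"{d}: {len(rep.screen)} variables, {len(rep.important)} important "
            f"(OOB error {rep.oob_error:.2%})"
        )
    lines.append("")
    lines.append(
        f"multi-domain package: {multi.table.p} variables -> refined set of "
        f"{len(multi.refined)}"
    )
    for stage, cls in multi.classifiers.items():
        for name, r in cls.items():
            if hasattr(r, "auc"):
                lines.append(
                    f"  {stage} {name}: AUC {r.auc:.2f}, "
                    f"sens {r.sensitivity:.0%}, spec {r.specificity:.0%}"
                )
    for key, res in multi.loocv.items():
        lines.append(f"  LOOCV {key}: accuracy {res['accuracy']:.0%}")
    spath = outdir / "summary.txt"
    spath.write_text("\n".join(lines) + "\n")
    written.append(spath)
    return written
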