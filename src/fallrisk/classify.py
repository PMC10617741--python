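"""Classifiers and the shared ROC / cross-validation evaluation layer.

Three classifiers distinguish fallers from non-fallers on a refined variable
set: a maximum-likelihood logistic regression (with VIF, AIC/BIC, McFadden
pseudo-R^2 and backward stepwise refinement), the random forest's
out-of-bag vote fraction, and the PLSCA first latent score.  All three are
evaluated with the empirical ROC curve: trapezoid AUC (equivalently the
Mann-Whitney concordance probability), a normal-approximation Mann-Whitney
p-value against AUC = 0.5, and the Youden-J optimal cutoff with its
sensitivity / specificity and confusion counts.  Logistic models are
additionally assessed by leave-one-out cross-validation at probability
cutoff 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .cohort import FeatureTable, zscore_columns
from .forest import fit_forest, oob_predictions
from .plsca import fit_plsca, latent_scores, zscore_vector


# -- ROC ---------------------------------------------------------------------

@dataclass
class RocReport:
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    confusion: dict[str, int]  # TP, FN, TN, FP
    degenerate: bool = False  # constant scores


def roc_auc(scores, labels) -> RocReport:
    """Empirical ROC analysis of a score vector against faller labels.

    AUC is the trapezoid area, identical to the Mann-Whitney U statistic
    scaled by 1/(n1 n2) with ties counted one half.  The p-value tests
    AUC = 0.5 by the normal-approximate Mann-Whitney test.  The optimal
    cutoff maximizes Youden's J = sensitivity + specificity - 1, taking the
    lowest threshold on ties; classification is score >= cutoff -> faller.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    degenerate = bool(np.all(scores == scores[0]))
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if degenerate:
        p_value = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ties warning at heavy ties
            p_value = float(
                stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").pvalue
            )
    j = tpr - fpr
    best_j = j.max()
    # ties -> lowest threshold; roc_curve thresholds are decreasing
    candidates = np.nonzero(j >= best_j - 1e-12)[0]
    idx = candidates[np.argmin(thr[candidates])]
    cutoff = float(thr[idx])
    report = confusion_at(scores, labels, cutoff)
    return RocReport(
        scores=scores,
        labels=labels,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        auc_p_value=p_value,
        cutoff=cutoff,
        sensitivity=report["sensitivity"],
        specificity=report["specificity"],
        confusion={k: report[k] for k in ("TP", "FN", "TN", "FP")},
        degenerate=degenerate,
    )


def confusion_at(scores, labels, cutoff: float) -> dict:
    """Confusion counts and rates classifying score >= cutoff as faller."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    return {
        "TP": tp,
        "FN": fn,
        "TN": tn,
        "FP": fp,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


# -- logistic regression -----------------------------------------------------

@dataclass
class LogisticReport:
    predictors: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    vif: dict[str, float]
    aic: float
    bic: float
    mcfadden_r2: float
    fitted_probabilities: np.ndarray
    llf: float
    llnull: float
    converged: bool
    separation_warning: bool = False
    elimination_path: list[str] = field(default_factory=list)


def _design(t: FeatureTable, predictors: list[str]) -> np.ndarray:
    x = np.column_stack([t.column(nm) for nm in predictors])
    if np.isnan(x).any():
        raise ValueError("missing cells among predictors; impute first")
    return x


def _predict(fit, exog=None) -> np.ndarray:
    with np.errstate(over="ignore"):
        return np.asarray(fit.predict() if exog is None else fit.predict(exog))


def variance_inflation(x: np.ndarray, names: list[str]) -> dict[str, float]:
    """VIF per predictor from auxiliary OLS regressions (with intercept)."""
    out = {}
    for j, nm in enumerate(names):
        others = np.delete(x, j, axis=1)
        aux = sm.OLS(x[:, j], sm.add_constant(others)).fit()
        r2 = min(aux.rsquared, 1 - 1e-12)
        out[nm] = float(1.0 / (1.0 - r2))
    return out


def _fit_logit(y: np.ndarray, design: np.ndarray):
    """Newton MLE with a quasi-Newton fallback for (quasi-)separated designs.

    Returns (fit, separation_suspected).  Overflow in the logistic cdf under
    huge linear predictors is benign saturation and silenced.
    """
    model = sm.Logit(y, design)
    with np.errstate(over="ignore"):
        try:
            return model.fit(disp=0, maxiter=200), False
        except np.linalg.LinAlgError:
            # singular Hessian under (quasi-)separation; BFGS still moves
            return model.fit(disp=0, maxiter=500, method="bfgs"), True


def logistic_fit(t: FeatureTable, predictors: list[str]) -> LogisticReport:
    """Maximum-likelihood binomial logit of faller status on the predictors."""
    y = t.y
    if predictors:
        x = _design(t, predictors)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), x])) < x.shape[1] + 1:
            raise ValueError("rank-deficient design (collinear or duplicated predictors)")
        if len(y) <= x.shape[1] + 1:
            raise ValueError("more predictors than the sample can support")
        design = sm.add_constant(x)
        names = ["const"] + list(predictors)
    else:
        design = np.ones((len(y), 1))
        names = ["const"]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit, separation = _fit_logit(y, design)
        separation = separation or any(
            "separat" in str(w.message).lower() for w in caught
        )
    coefs = dict(zip(names, np.asarray(fit.params, dtype=float)))
    pvals = dict(zip(names, np.asarray(fit.pvalues, dtype=float)))
    vif = variance_inflation(x, list(predictors)) if len(predictors) > 1 else (
        {predictors[0]: 1.0} if predictors else {}
    )
    return LogisticReport(
        predictors=list(predictors),
        coefficients=coefs,
        p_values=pvals,
        vif=vif,
        aic=float(fit.aic),
        bic=float(fit.bic),
        mcfadden_r2=float(1.0 - fit.llf / fit.llnull) if fit.llnull != 0 else 0.0,
        fitted_probabilities=_predict(fit),
        llf=float(fit.llf),
        llnull=float(fit.llnull),
        converged=bool(fit.mle_retvals.get("converged", True)),
        separation_warning=separation,
    )


def stepwise_backward(
    t: FeatureTable, predictors: list[str], criterion: str = "aic"
) -> LogisticReport:
    """Backward elimination minimizing AIC or BIC.

    At each step the predictor whose removal most decreases the criterion is
    dropped; stops when no removal decreases it.  Ties are broken by removing
    the predictor with the largest p-value in the current model, so the path
    is deterministic.  The elimination path is recorded on the report.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    current = list(predictors)
    report = logistic_fit(t, current)
    path: list[str] = []
    while current:
        best_crit = getattr(report, criterion)
        best_candidate: str | None = None
        best_report = None
        for nm in current:
            reduced = [v for v in current if v != nm]
            cand = logistic_fit(t, reduced)
            c = getattr(cand, criterion)
            if c < best_crit - 1e-10:
                best_crit, best_candidate, best_report = c, nm, cand
            elif best_candidate is not None and abs(c - best_crit) <= 1e-10:
                # tie: drop the predictor with the larger p-value
                if report.p_values.get(nm, 0) > report.p_values.get(best_candidate, 0):
                    best_candidate, best_report = nm, cand
        if best_candidate is None:
            break
        path.append(best_candidate)
        current = [v for v in current if v != best_candidate]
        report = best_report
    report.elimination_path = path
    return report


def loocv_accuracy(
    t: FeatureTable, predictors: list[str], cutoff: float = 0.5
) -> tuple[float, int]:
    """Leave-one-out cross-validated accuracy of the logistic model.

    Each participant is predicted from a model fitted on the other n - 1,
    classified faller at probability >= cutoff (0.5, not the in-sample
    Youden cutoff, to avoid information leakage).  Returns (accuracy,
    number of non-convergent folds).  Deterministic given the data.
    """
    y = t.y
    x = _design(t, predictors)
    n = len(y)
    correct = 0
    non_converged = 0
    for i in range(n):
        keep = np.arange(n) != i
        design = sm.add_constant(x[keep], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit, fell_back = _fit_logit(y[keep], design)
                if fell_back or not fit.mle_retvals.get("converged", True):
                    non_converged += 1
                prob = float(
                    _predict(fit, np.concatenate([[1.0], x[i]])[None, :])[0]
                )
            except Exception:
                non_converged += 1
                prob = float(np.mean(y[keep]))  # fallback: base rate
        if (prob >= cutoff) == bool(y[i]):
            correct += 1
    return correct / n, non_converged


# -- score-based classifiers -------------------------------------------------

def plsca_classifier(t: FeatureTable, predictors: list[str]) -> RocReport:
    """PLSCA latent-score classifier: ROC of the first-component projection.

    The group indicator (z-scored) is the X block and the z-scored predictor
    table the Y block; participant scores on the first right salience,
    oriented to correlate positively with faller coding, feed the ROC.
    """
    sub = zscore_columns(t.subset(predictors))
    if sub.mask.any():
        raise ValueError("missing cells among predictors; impute first")
    y = t.y
    res = fit_plsca(zscore_vector(y), sub.values)
    scores = latent_scores(res, sub.values, orient=y)
    return roc_auc(scores, y)


def rf_classifier(
    t: FeatureTable, predictors: list[str], n_trees: int = 500, seed: int | None = None
) -> RocReport:
    """Random-forest classifier: ROC of the out-of-bag faller vote fraction."""
    report = fit_forest(t.subset(predictors), n_trees=n_trees, seed=seed)
    votes = oob_predictions(report)
    if np.isnan(votes).any():
        raise ValueError("some participants were never out-of-bag; increase n_trees")
    return roc_auc(votes, t.y)
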