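"""Random-forest importance engine with out-of-bag validation.

A 500-tree classification forest (Gini impurity, sqrt(p) features tried per
split, bootstrap sampling with replacement, unlimited depth) ranks variables
by mean decrease in Gini impurity.  The forest's built-in out-of-bag (OOB)
votes provide internal cross-validation: each participant is scored only by
trees whose bootstrap sample excluded her.  The OOB error is tested against
the no-information (majority-class) rate with a one-sided binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from .cohort import FeatureTable


@dataclass
class ForestReport:
    names: list[str]
    importance: np.ndarray  # mean decrease in Gini
    oob_error: float
    oob_p_value: float
    oob_votes: np.ndarray  # per-participant faller vote fraction (NaN if never OOB)
    n_trees: int
    seed: int | None
    model: RandomForestClassifier


def fit_forest(
    t: FeatureTable,
    n_trees: int = 500,
    seed: int | None = None,
    max_features: str | int = "sqrt",
) -> ForestReport:
    """Fit the classification forest on a complete (imputed) table."""
    if t.mask.any():
        raise ValueError("table has missing cells; impute before fitting")
    y = t.y
    if len(set(y)) < 2:
        raise ValueError("both groups must be present")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=max_features,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    )
    rf.fit(t.values, y)
    # faller (class 1) OOB vote fraction; rows never OOB come back as NaN
    votes = rf.oob_decision_function_[:, list(rf.classes_).index(1)]
    covered = ~np.isnan(votes)
    pred = (votes[covered] >= 0.5).astype(int)
    n_correct = int((pred == y[covered]).sum())
    oob_error = 1.0 - n_correct / covered.sum()
    majority = max(np.mean(y), 1 - np.mean(y))
    oob_p = binomtest(
        n_correct, int(covered.sum()), float(majority), alternative="greater"
    ).pvalue
    return ForestReport(
        names=t.names,
        importance=rf.feature_importances_.copy(),
        oob_error=float(oob_error),
        oob_p_value=float(oob_p),
        oob_votes=votes,
        n_trees=n_trees,
        seed=seed,
        model=rf,
    )


def oob_predictions(report: ForestReport) -> np.ndarray:
    """Per-participant OOB faller probability (vote fraction).

    NaN marks participants never out-of-bag, which only happens at very
    small tree counts; at 500 trees on n = 60 coverage is complete.
    """
    return report.oob_votes.copy()
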