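"""Jenks natural-breaks elbow selection and union refinement.

Importance scores from each ranking engine are split into "important" vs
"not important" by the exact Fisher-Jenks optimum (the 1-D classification
minimizing within-class sum of squared deviations); variables strictly above
the break form the selected set.  The selections of the two engines are then
combined by set union into the refined variable list.  A manual-override
cutoff is accepted, reflecting the subjective validation step a human
analyst may apply to the scree plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def jenks_breaks(scores, n_classes: int = 2) -> list[float]:
    """Exact Fisher-Jenks natural breaks via dynamic programming.

    Minimizes the total within-class sum of squared deviations over all
    partitions of the sorted values into ``n_classes`` contiguous classes.
    Returns the upper boundaries (maximum member) of the first
    ``n_classes - 1`` classes, ascending.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    n = len(x)
    if len(np.unique(x)) < n_classes:
        raise ValueError("fewer distinct values than classes")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")

    # prefix sums for O(1) SSD of any contiguous slice
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def ssd(i: int, j: int) -> float:
        """within-class SSD of x[i:j] (j exclusive)"""
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = float("inf")
    # cost[k][j]: best total SSD of x[:j] split into k classes
    cost = np.full((n_classes + 1, n + 1), INF)
    split = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for k in range(1, n_classes + 1):
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1][i] + ssd(i, j)
                if c < best:
                    best, arg = c, i
            cost[k][j] = best
            split[k][j] = arg
    # recover class boundaries
    bounds = []
    j = n
    for k in range(n_classes, 1, -1):
        i = split[k][j]
        bounds.append(float(x[i - 1]))  # max of the class ending at i-1
        j = i
    return bounds[::-1]


@dataclass
class SelectionResult:
    """An engine's importance scores, the Jenks break, and the selected set."""

    names: list[str]
    scores: np.ndarray
    break_value: float
    selected: list[str]
    engine: str
    manual_cutoff: float | None = None


def select_above_break(
    names,
    scores,
    engine: str = "",
    cutoff: float | None = None,
) -> SelectionResult:
    """Select the variables strictly above the 2-class Jenks break.

    Ties at the break go below (conservative).  ``cutoff`` overrides the
    Jenks break with a manually validated value; the override is recorded in
    the result.
    """
    scores = np.asarray(scores, dtype=float)
    if len(names) != len(scores):
        raise ValueError("names/scores length mismatch")
    if cutoff is None:
        brk = jenks_breaks(scores, n_classes=2)[0]
    else:
        brk = float(cutoff)
    selected = [nm for nm, s in zip(names, scores) if s > brk]
    return SelectionResult(
        names=list(names),
        scores=scores,
        break_value=brk,
        selected=selected,
        engine=engine,
        manual_cutoff=cutoff,
    )


def union_important(a: SelectionResult, b: SelectionResult) -> tuple[list[str], dict[str, str]]:
    """Union of two engines' selections with per-variable provenance.

    Returns the de-duplicated refined variable list (ordered: common first,
    then a-only, then b-only, each in original score order) and a mapping
    variable -> "both" | engine-a-only | engine-b-only.
    """
    if set(a.names) != set(b.names):
        raise ValueError("selections are over different variable universes")
    sa, sb = set(a.selected), set(b.selected)
    provenance: dict[str, str] = {}
    ordered: list[str] = []
    for nm in a.names:
        if nm in sa and nm in sb:
            provenance[nm] = "both"
            ordered.append(nm)
    for nm in a.names:
        if nm in sa and nm not in sb:
            provenance[nm] = f"{a.engine or 'a'}-only"
            ordered.append(nm)
    for nm in b.names:
        if nm in sb and nm not in sa:
            provenance[nm] = f"{b.engine or 'b'}-only"
            ordered.append(nm)
    return ordered, provenance
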