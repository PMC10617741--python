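"""Dual variable-importance ranking and Jenks elbow selection on one domain.

The random forest ranks variables by mean decrease in Gini impurity; the
leave-one-variable-out (LOVO) PLSCA ranks them by the drop in singular-value
inertia when each is excluded.  The exact Fisher-Jenks 2-class break plays
the role of the scree-plot elbow, and the union of both selections is the
domain's refined variable set.
"""

import fallrisk as fr
from fallrisk.selection import select_above_break, union_important

cfg = fr.builtin_fixture_config(n_nuisance=3, missing_rate=0.0, seed=5)
table = fr.generate_cohort(cfg)
gait = fr.partition_domains(table)["gait"]

forest = fr.fit_forest(gait, n_trees=500, seed=0)
rf_sel = select_above_break(forest.names, forest.importance, engine="rf")
print(f"random forest: {len(rf_sel.selected)} of {gait.p} variables above "
      f"the Jenks break ({rf_sel.break_value:.4f})")

z = fr.zscore_columns(gait)
lovo = fr.lovo_importance(fr.zscore_vector(gait.y), z.values, names=gait.names)
lovo_sel = select_above_break(lovo.names, lovo.importance, engine="lovo")
print(f"LOVO PLSCA:    {len(lovo_sel.selected)} variables above the break "
      f"({lovo_sel.break_value:.4f}); baseline inertia {lovo.baseline_inertia:.3f}")

union, provenance = union_important(rf_sel, lovo_sel)
print(f"\nrefined set ({len(union)} variables):")
for nm in union:
    print(f"  {nm:<45} [{provenance[nm]}]")
# Nuisance variables carry no group effect and should stay below the breaks.
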