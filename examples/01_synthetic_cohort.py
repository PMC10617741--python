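"""Generate a synthetic faller / non-faller cohort and inspect its structure.

The built-in configuration encodes the published per-group means and SDs for
every variable of the multi-domain package (51 variables over five domains)
plus the baseline descriptives, with block multicollinearity and MCAR
missingness.  Group sizes default to 21 fallers vs 39 non-fallers.
"""

import fallrisk as fr

cfg = fr.builtin_fixture_config(n_nuisance=2, missing_rate=0.02, seed=42)
table = fr.generate_cohort(cfg)

print(f"cohort: {table.n} participants ({table.n_fallers} fallers, "
      f"{table.n_nonfallers} non-fallers), {table.p} variables")
print(f"missing cells: {int(table.mask.sum())} "
      f"({table.mask.mean():.1%} of the matrix)")

part = fr.partition_domains(table)
for dom, sub in part.items():
    print(f"  {dom:>16}: {sub.p} variables")

# The per-domain counts include 2 appended "nuisance" variables per domain
# with no group effect; the selection stages are expected to discard them.
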