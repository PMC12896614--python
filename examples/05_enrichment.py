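"""Chi-square gene-set enrichment, including a published-table check.

The enrichment stage crosses set membership with per-gene significance in
a 2x2 table and applies Pearson's chi-square without continuity
correction.  As a calibration, the first block below feeds in the margins
of a published risk-gene table (93 of 563 set genes significant vs 2794
of 32,825 background genes) and reproduces its printed statistic.
"""

from clonediff import ContingencyTable, GeneSet, chisq_test, run_enrichment_suite
import pandas as pd
import numpy as np

# -- published margins as input -----------------------------------------
res = chisq_test(ContingencyTable(93, 563 - 93, 2794, 32_825 - 2794))
print(f"published-table check: chi2 = {res.chi2:.2f}, DF = {res.df}, "
      f"p = {res.p:.2g}, {res.direction}")

# -- enrichment on a simulated classification ---------------------------
rng = np.random.default_rng(5)
universe = [f"G{i:04d}" for i in range(2000)]
members = frozenset(rng.choice(universe, 80, replace=False))
rows = []
for g in universe:
    p_sig = 0.35 if g in members else 0.08  # strong planted enrichment
    rows.append((g, "2-vs-0", bool(rng.random() < p_sig), False))
classes = pd.DataFrame(rows, columns=["gene", "comparison", "de", "da"])

suite = run_enrichment_suite(classes, [GeneSet("planted_risk_set", members)],
                             modes=["DE"])
row = suite.iloc[0]
print(f"\nsimulated panel:        a={row['a']} b={row['b']} c={row['c']} d={row['d']}")
print(f"chi2 = {row['chi2']:.2f}, p = {row['p']:.2g}, {row['direction']}")

print(
    "\n'a' counts set genes that are differentially expressed; the test"
    "\nasks whether that fraction exceeds the background fraction c/(c+d)."
)
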