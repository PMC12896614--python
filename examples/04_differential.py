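"""Group-model differential expression under the exon-count hypothesis.

Thirty genes carry a planted +2 log2-unit shift in the double-targeted
clones; the group-means linear model with a 2-vs-0 contrast and BH FDR
should recover essentially all of them.
"""

from clonediff import (
    GroupModelSpec,
    PanelConfig,
    default_truth,
    flag_detected_features,
    generate_panel,
    reduce_transcriptome,
    run_differential,
    second_pass,
    simulate_expression,
    upper_quartile_log,
)

panel = generate_panel(PanelConfig(seed=1))
truth = default_truth(200, 20, seed=4, n_de=30, de_effect=2.0,
                      n_gradient=0, n_outliers=0)
sim = simulate_expression(panel, 200, 2, truth, dispersion=0.4, seed=4)

reduced = reduce_transcriptome(sim.catalog, flag_detected_features(sim.coverage))
norm = upper_quartile_log(second_pass(sim.expression, reduced).genes)

spec = GroupModelSpec("H4", panel.groups("H4"), contrasts=(("2", "0"),))
res = run_differential(norm.normalized_log, spec, alpha=0.05).set_index("feature")

planted = {e.gene for e in truth.de_genes}
called = set(res.index[res["significant"]])
print(f"genes tested:            {len(res)}")
print(f"planted effects:         {len(planted)}")
print(f"significant (FDR<0.05):  {len(called)}")
print(f"planted and recovered:   {len(planted & called)}")
print(f"false discoveries:       {len(called - planted)}")

top = res.loc[sorted(planted & called, key=lambda g: res.loc[g, 'fdr'])[:3]]
print("\nthree strongest planted recoveries:")
print(top[["estimate", "statistic", "p", "fdr"]].round(4).to_string())

extra = res.loc[sorted(called - planted)]
print(f"\nmedian estimate among extra discoveries: "
      f"{extra['estimate'].median():.2f} (planted median: "
      f"{res.loc[sorted(planted & called), 'estimate'].median():.2f})")

print(
    "\n'estimate' is the difference of group means on the normalized log2"
    "\nscale, so values near 2 match the planted effect; FDR is BH-adjusted"
    "\nwithin this comparison.  The extra discoveries with small negative"
    "\nestimates are the compositional echo of TPM: thirty genes gaining"
    "\nfourfold expression in one group pushes every other gene's relative"
    "\nabundance slightly down in that group — a genuine property of"
    "\nwithin-sample-normalized data, not a testing artifact."
)
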