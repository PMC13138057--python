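"""Link TF motif accessibility to target gene-set expression.

A planted TF couples its target-set expression to its per-cell motif
accessibility only in the treated condition (slope 1, noise sd 1, so the
realized R^2 converges to 0.5); 20 decoy TFs have no coupling.  The
relevance table ranks TFs by the treatment-induced change in R^2.
"""

import scidentity as sid

_, truth = sid.generate_bulk(n_genes=60, n_samples=8, k_true=2, seed=1)
data = sid.generate_tf_multiome(truth, seed=1)
results = sid.tf_relevance_table(
    data.accessibility, data.expr, data.targets, data.pathway_genes,
    control="control", treatments=["treated"], seed=1,
)
df = sid.linkage_to_frame(results).sort_values("delta_r2_treated",
                                               ascending=False)
cols = ["accessibility_diff", "broad_p_adj", "pathway_p_adj",
        "r2_control", "r2_treated", "delta_r2_treated"]
print(df[cols].head(3).round(4))
print(f"\nplanted TF: {data.planted_tf}; "
      f"top delta R^2: {df.index[0]} ({df['delta_r2_treated'].iloc[0]:.3f})")
# The planted TF shows accessibility gain ~1, treated R^2 ~0.5 (the
# variance-ratio limit) and significant target upregulation; decoys sit at
# delta R^2 ~0 with null p-values.
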