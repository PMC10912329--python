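"""Which genes drive each predicted protein?

Computes the closed-form Jacobian of predicted ADT with respect to each
input gene (averaged over cells) and ranks genes by absolute importance for
one protein. Because the synthetic ground truth plants marker-gene blocks
per cell type, the top-ranked genes should come from the protein's own
cell type's marker block.
"""

import adtpred as ap

cfg = ap.SyntheticConfig(seed=1)
ds = ap.generate(cfg)
pipe = ap.fit_pipeline(ds.gex, ds.adt, ap.PipelineConfig(n_components=10, random_seed=1))

norm = ap.normalize_gex(ds.gex)
# averaging the per-cell Jacobian over a subsample of cells is enough
sub = ap.NormalizedGEX(norm.values[:200], norm.gene_names,
                       norm.barcodes[:200], norm.size_factors[:200])
fi = ap.feature_importance(pipe, sub, aggregation="mean_over_cells")

protein = pipe.protein_names[0]
true_markers = set(ds.truth.protein_marker_genes[protein])
top = ap.top_features(fi, protein, n=10)

print(f"top 10 genes for {protein} (signed d prediction / d gene):")
for _, row in top.iterrows():
    flag = "marker" if row["gene"] in true_markers else ""
    print(f"  {row['gene']}: {row['importance']:+.4f} {flag}")
hits = sum(g in true_markers for g in top["gene"])
print(f"\n{hits}/10 of the top genes are true markers of {protein}'s cell type")
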