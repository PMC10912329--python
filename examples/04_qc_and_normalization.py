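"""Per-cell quality control and the two normalizations.

Builds a GEX matrix with planted low-quality cells (one very deep cell and
one high-mitochondrial cell), filters them with the scaled-MAD outlier
rule, then shows size-factor + log1p normalization of GEX and the centered
log-ratio transform of ADT counts.
"""

import numpy as np

import adtpred as ap

rng = np.random.default_rng(3)
counts = rng.poisson(20, (200, 300))
features = ["MT-CO1", "MT-ND1"] + [f"GENE{i}" for i in range(298)]
counts[0] *= 40                 # a suspiciously deep cell (likely doublet)
counts[1, :2] = counts[1].sum() # a cell dominated by mitochondrial reads
gex = ap.CountMatrix(counts, features, [f"c{i}" for i in range(200)], "GEX")

metrics = ap.compute_qc_metrics(gex)
print("per-cell QC metrics (first 3 cells):")
print(metrics.head(3).to_string(), "\n")

filtered, report = ap.qc_filter(gex, ap.QCConfig(nmads=3))
print(f"cells kept: {report['n_cells_kept']}/{report['n_cells_in']}")
print(f"removed per metric: {report['removed_by_metric']}\n")

norm = ap.normalize_gex(filtered)
print(f"size factors: median {np.median(norm.size_factors):.2f}, "
      f"range [{norm.size_factors.min():.2f}, {norm.size_factors.max():.2f}]")

adt = ap.CountMatrix(rng.poisson(60, (filtered.n_cells, 5)),
                     [f"P{i}" for i in range(5)], filtered.barcodes, "ADT")
clr = ap.clr_transform(adt, margin="across_cells")
print(f"CLR-ADT values: mean {clr.values.mean():.3f}, sd {clr.values.std():.3f} "
      f"(centered per protein across cells)")
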