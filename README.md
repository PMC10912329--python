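# adtpred

Predict single-cell surface-protein abundance from gene expression.

CITE-seq measures RNA and surface proteins (antibody-derived tags, ADT)
in the same cells, but most single-cell experiments only measure RNA.
`adtpred` trains a simple, fast, interpretable model on paired CITE-seq
data and then imputes CLR-normalized ADT levels for any RNA-only
experiment. It is aimed at single-cell analysts who want protein-level
readouts (e.g. CD3/CD19/CD14 gating) without an antibody panel, and at
method developers who need a transparent linear baseline.

## The model

Three linear steps, fitted on paired GEX/ADT counts:

```
X  = log1p(counts / size_factor)        # GEX normalization
L  = X V                                # truncated SVD, k components (no centering)
Z  = (L − μ_cell) / σ_cell              # z-score each cell's reduced vector
Ŷ  = Z W + b                            # OLS onto CLR-normalized ADT
```

Because every step is linear (or has an exact closed-form derivative),
the Jacobian ∂Ŷ/∂X = V · J_z · W is available analytically and serves as
a per-gene, per-protein feature-importance matrix. The package also
ships scaled-MAD quality control, evaluation metrics (RMSE, per-protein
and per-cell Pearson r), an iterative dropout-robustness simulation, and
a seeded generator of realistic paired synthetic data.

## Worked example

```python
import numpy as np
import adtpred as ap

cfg = ap.SyntheticConfig(seed=0)          # 2000 cells, 1500 genes, 20 proteins
ds = ap.generate(cfg)
train, test = ap.train_test_split(ds, test_fraction=0.5, seed=0)

pipe = ap.fit_pipeline(train.gex, train.adt,
                       ap.PipelineConfig(n_components=10, random_seed=0))
pred = ap.predict_adt(pipe, test.gex)
report = ap.evaluate(pred, ap.clr_transform(test.adt))
print(f"RMSE {report.rmse_overall:.3f}, "
      f"median per-protein r {np.nanmedian(report.pearson_per_protein):.3f}")
```

prints

```
RMSE 0.597, median per-protein r 0.816
```

meaning: on 1000 held-out cells the predictions deviate from measured
CLR-ADT by 0.60 on average, and for a typical protein the predicted and
measured values correlate at r ≈ 0.82 across cells — despite the input
GEX matrix being 90% zeros. The `examples/` directory has one short
script per capability (fit/predict, feature importance, dropout
robustness, QC and normalization); each prints its numbers with a line
on what they mean.

## Command line

The same workflow is available as a thin CLI over 10x-style MTX triplet
directories:

```sh
adtpred simulate --out-dir data --seed 0
adtpred fit data/gex data/adt --model-out model.npz --n-components 10
adtpred predict model.npz data/gex --out pred.csv
adtpred evaluate pred.csv data/adt --out eval.json
adtpred importance model.npz data/gex --out importance.csv
adtpred dropout model.npz data/gex data/adt --out curve.json
```

All outputs are plain CSV/JSON with a provenance stamp (package version,
config hash, seed); the model file is a `.npz` container that round-trips
bit-exactly.

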