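# Methods

## The prediction model

`adtpred` predicts per-cell surface-protein abundance (ADT, on the CLR
scale) from gene expression (GEX UMI counts) with a three-step linear
pipeline:

1. **Truncated SVD.** The normalized GEX matrix `X` (cells × genes,
   log1p of size-factor-scaled counts) is factorized without
   mean-centering; the top-k right singular vectors `V` (genes × k) give
   the reduced representation `L = X V`. This is deliberately *not* PCA:
   no column means are subtracted, so the first component typically
   captures overall expression magnitude. The default k is 300, the
   dimensionality appropriate for full-scale CITE-seq experiments; on
   smaller data k is clamped down to `min(cells − 1, genes)` with a
   warning, and the clamping is recorded in the model file. An exact
   LAPACK decomposition is used whenever the smaller matrix dimension is
   ≤ 1000; above that a seeded randomized solver keeps fitting fast and
   reproducible.
2. **Cell-wise z-score.** Each cell's reduced vector is standardized to
   mean 0, sd 1 (population sd by default; sample sd available via
   `zscore_ddof="sample"`). This removes per-cell scale and makes every
   cell's prediction independent of every other cell at prediction time.
   A constant reduced vector (a degenerate cell) maps to all-zero scores
   with a warning rather than NaN, so one empty cell cannot poison a
   batch prediction.
3. **Multivariate linear regression.** Ordinary least squares with
   intercept maps the standardized reduced space to CLR-normalized ADT,
   all proteins in one solve. The solver is an orthogonal-decomposition
   least squares (`lstsq`), not explicit normal equations; the
   normal-equations form appears only as an independent oracle in the
   tests.

Prediction on new data aligns genes **by name**: trained genes missing
from the input are zero-filled (equivalent to restricting the loading
rows to the common genes), unknown input genes are dropped, and an
overlap below 30% of the trained gene universe (configurable) is an
error rather than a silently degraded prediction. Raw counts are
normalized with the model's stored settings before projection; size
factors use the input cohort's median, a choice recorded in the model
metadata.

## Normalizations

- **GEX**: per-cell size factors (library size over the median library
  size) divide the counts, then log1p. Externally computed size factors
  — e.g. pooled deconvolution factors — can be injected; the pipeline
  contract is only "divide by size factor, log1p".
- **ADT**: centered log-ratio in the log1p dialect,
  `clr(x)_i = log1p(x_i / exp(mean_j log1p(x_j)))`, so zero counts stay
  finite without pseudocounts. The default margin centers each protein
  across cells; the within-cell margin is available because usage of
  the term varies between implementations.

## Quality control

Three per-cell metrics: total counts, detected features, percent
mitochondrial counts (case-insensitive `MT-` prefix by default, which
also catches mouse `mt-`). Outliers are cells more than 3 scaled MADs
(MAD × 1.4826, the normal-consistency constant) from the median; counts
and detected features are tested two-sided on the log1p scale, percent
mitochondrial one-sided (upper) on the raw scale. Thresholds are
computed once on the full input and then applied, so filtering is
deterministic and idempotent under the frozen thresholds. With a zero
MAD the rule degenerates to keeping only values at (or below, for the
one-sided metric) the median — the conventional behaviour of
scaled-MAD filters on tied data.

## Feature importance

Because the pipeline is a composition of three maps, the Jacobian of
predicted ADT with respect to the input genes factorizes as
`V · J_z(x) · W`: the TSVD Jacobian is the loading matrix, the
regression Jacobian is the weight matrix, and the z-score Jacobian has
the closed form `J_ij = (δ_ij − 1/k − z_i z_j / k) / σ` (population sd;
the sample-sd variant replaces the last `k` by `k − 1`). The closed
form replaces automatic differentiation — for a linear pipeline the
derivative is available exactly, and equivalence is enforced by
finite-difference oracle tests rather than assumed.

`J_z` depends on the cell, so the full Jacobian is per-cell. The
default report averages over the provided cells (order-independent and
unbiased); evaluation at the mean reduced vector (`at_reference_cell`)
and the raw per-cell stack are also available, since which summary a
study wants is situational. Gene rankings sort by absolute aggregated
importance with the sign retained (magnitude measures influence, sign
is biologically informative); ties break lexicographically so rankings
are stable across runs.

## Evaluation and the dropout simulation

Accuracy is RMSE over all cells × proteins plus Pearson correlations
per protein (across cells) and per cell (across proteins). Correlations
of constant vectors are flagged undefined (NaN with an exclusion count)
and excluded from summaries, never propagated.

The dropout simulation degrades the GEX counts iteratively: each round
flags every currently non-zero entry independently with probability
`p_zero = 0.1` and zeroes the flagged entries, then re-runs the *full*
prediction path — including re-normalization, so size factors shrink
with depth, mirroring what happens when the tool is applied to
shallower data. The loop stops when the realized dropout rate exceeds
0.99. The rate is defined over the whole matrix (zeros / total entries,
originally-zero entries included), and the definition is embedded in
the output so alternative conventions are auditable. Cells thinned to
zero total counts are retained with all-zero normalized vectors; their
per-cell correlations are flagged undefined rather than dropped.

## The synthetic generator

The generator emulates the regime the model assumes: cells occupy a
shared rank-`n_factors` latent space (cell-type centroids, per-cell
Gaussian jitter), gene expression rates follow a softplus link of the
latent factors with negative-binomial counts, per-cell lognormal depth
variation (σ = 0.3), and uniform extra zeroing up to a target sparsity;
ADT counts follow an exponential link of a latent signal that is
*linear* in the factors plus Gaussian noise, scaled by one global
constant (so log-rates stay affine in the signal) and the same style of
per-cell depth factor. Every protein belongs to one cell type, and each
cell type carries disjoint marker-gene and marker-protein blocks whose
loadings are boosted along the type's centroid direction; the blocks
are recorded in the ground truth for interpretability checks.

Default conditions — 2000 cells, 1500 genes, 20 proteins, 10 factors, 4
cell types, ~5000 UMIs and ~1000 ADT counts per cell, inverse-dispersion
10 (a biological CV around 0.3, typical of UMI data), 90% GEX sparsity
— are the package's reference study conditions and are used as-is by
the test suite and `scripts/acceptance.py`. At this scale the whole
fit-evaluate-interpret-degrade cycle runs in seconds on one core, which
is why the reference problem is this size rather than a full-scale
dataset.

What the generator does **not** emulate: batch effects, doublets,
ambient RNA/antibody background, isotype controls, spatial structure,
and gene-level mean-variance trends beyond the single dispersion
parameter. Passing tests on this data therefore show that the pipeline
recovers a low-rank linear GEX→ADT relationship through realistic count
noise and sparsity — not that it handles every artifact of real
CITE-seq experiments.

### What recovery looks like under these conditions

At the reference conditions the held-out median per-protein Pearson r
is ≈ 0.81–0.83. The binding constraint is the 90% GEX sparsity: the
uniform extra zeroing discards most of the per-cell information, and
removing the latent ADT noise entirely (adt_noise_sd = 0) barely moves
the result, while generating without the extra zeroing (≈ 35% natural
NB sparsity) lifts it to ≈ 0.94. This is a property of the study
conditions, not of the implementation — the linear-algebra components
are verified against independent oracles (full SVD, normal equations,
finite differences) to 1e-5–1e-8. It mirrors the practical situation:
on shallow, sparse data the method's accuracy is data-limited.

## Numerical choices

- SVD sign ambiguity is resolved by making each loading column's
  largest-magnitude entry positive, so refits are bit-identical.
- Model files are `.npz` containers with raw float64 arrays plus a JSON
  metadata block; round-trips are bit-exact, and an unknown format
  version is a hard error, never silent coercion.
- Duplicate feature names on load are de-duplicated by appending `.1`,
  `.2`, … in file order; the original names are kept in a sidecar
  field and written back on export.
- Matrices with ≥ 2³¹ stored entries are outside the tested envelope of
  the MTX writer and are rejected explicitly.

## Known limitations

- Only GEX→ADT prediction; no ATAC or reverse-direction models.
- No empty-droplet calling, doublet detection, batch integration,
  clustering or cell-type annotation — those are upstream steps this
  package expects to have been done by dedicated tools.
- The default size factors are library-size/median; pooled
  deconvolution factors must be computed externally and injected.
- Dense in-memory matrices: the tested envelope is desk-scale
  (≈ 10⁴ cells × 10⁴ genes), not atlas-scale.
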