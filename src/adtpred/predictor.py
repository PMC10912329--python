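"""The core prediction pipeline: TSVD -> cell-wise z-score -> linear regression.

Protein abundance is predicted from gene expression in three linear-algebra
steps. A truncated SVD (no mean-centering — this is not PCA) projects the
normalized GEX matrix onto its top-k right singular vectors; each cell's
reduced vector is then z-scored to mean 0 / sd 1; finally an ordinary
least-squares multivariate regression maps the standardized reduced space
to CLR-normalized ADT values. A trained pipeline can be applied to any GEX
matrix: genes are aligned by name, missing trained genes are zero-filled,
and predictions land on the CLR scale of the training proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.utils.extmath import randomized_svd

from ._errors import AlignmentError, FitError
from .io import CountMatrix, TrainedPipeline
from .preprocess import CLRMatrix, NormalizedGEX, clr_transform, normalize_gex

logger = logging.getLogger(__name__)

#: Below this smallest matrix dimension the exact LAPACK SVD is used;
#: above it, a seeded randomized solver.
EXACT_SVD_MAX_DIM = 1000


@dataclass
class PipelineConfig:
    """Hyper-parameters of the prediction pipeline.

    ``n_components`` defaults to 300, the reduced dimensionality used for
    full-scale CITE-seq data; it is clamped down (with a warning) when the
    training data are smaller, unless ``clamp_components`` is disabled, in
    which case an oversized request is an error. ``zscore_ddof`` selects
    population (ddof 0) or sample (ddof 1) standard deviation in the
    cell-wise standardization.
    """

    n_components: int = 300
    zscore_ddof: Literal["population", "sample"] = "population"
    min_gene_overlap_fraction: float = 0.3
    random_seed: int = 0
    clamp_components: bool = True
    clr_margin: Literal["across_cells", "within_cell"] = "across_cells"

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be a positive integer")
        if not (0 < self.min_gene_overlap_fraction <= 1):
            raise ValueError("min_gene_overlap_fraction must be in (0, 1]")
        if self.zscore_ddof not in ("population", "sample"):
            raise ValueError("zscore_ddof must be 'population' or 'sample'")


@dataclass
class LowDimMatrix:
    """Cells x k matrix in the reduced (or standardized reduced) space."""

    values: np.ndarray
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class PredictedADT:
    """Predicted protein abundances on the CLR scale."""

    values: np.ndarray
    protein_names: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class AlignmentPlan:
    """How input gene columns map onto a pipeline's trained gene universe.

    ``trained_to_input[i]`` is the input column holding trained gene ``i``,
    or -1 when the gene is absent from the input (its column is zero-filled
    at prediction time).
    """

    trained_to_input: np.ndarray
    missing_genes: list[str]
    dropped_input_genes: list[str]
    overlap_fraction: float


def _fix_signs(loadings: np.ndarray, low_dim: np.ndarray):
    """Deterministic sign convention: each loading column's largest-|.|
    entry is made positive. Removes the solver's sign ambiguity."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            loadings[:, j] = -col
            low_dim[:, j] = -low_dim[:, j]
    return loadings, low_dim


def fit_tsvd(X, k: int, seed: int = 0):
    """Fit a rank-k truncated SVD (uncentered) of a cells x genes matrix.

    Returns ``(loadings, low_dim)`` where ``loadings`` (genes x k) holds the
    top-k right singular vectors and ``low_dim = X @ loadings``. The exact
    LAPACK decomposition is used when the smaller matrix dimension is at
    most 1000; larger problems use a seeded randomized solver.
    """
    barcodes = None
    if isinstance(X, NormalizedGEX):
        barcodes = X.barcodes
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    n_cells, n_genes = X.shape
    k_max = min(n_cells - 1, n_genes)
    if k > k_max:
        raise FitError(
            f"n_components={k} exceeds the admissible bound min(cells-1, genes)={k_max}"
        )
    if not np.all(np.isfinite(X)):
        raise FitError("input matrix contains non-finite values")
    if min(n_cells, n_genes) <= EXACT_SVD_MAX_DIM:
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        loadings = vt[:k].T.copy()
    else:
        _, _, vt = randomized_svd(X, n_components=k, random_state=seed)
        loadings = vt.T.copy()
    low_dim = X @ loadings
    loadings, low_dim = _fix_signs(loadings, low_dim)
    return loadings, LowDimMatrix(low_dim, barcodes or [str(i) for i in range(n_cells)])


def zscore_rows(values: np.ndarray, ddof: str = "population") -> np.ndarray:
    """Standardize each row to mean 0, sd 1. Constant rows map to zeros."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[1] < 2:
        raise FitError("cell-wise z-score is undefined with a single component")
    nddof = 0 if ddof == "population" else 1
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=nddof, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning(
            "%d cell(s) have a constant reduced vector; z-scores set to 0",
            int(constant.sum()),
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (values - mu) / safe_sd
    out[constant] = 0.0
    return out


def zscore_cells(L: LowDimMatrix, ddof: str = "population") -> LowDimMatrix:
    """Cell-wise z-score of a reduced matrix; see :func:`zscore_rows`."""
    return LowDimMatrix(zscore_rows(L.values, ddof), L.barcodes)


def fit_linear(Z: LowDimMatrix, Y: CLRMatrix):
    """OLS with intercept mapping the standardized reduced space to CLR-ADT.

    Each protein is fitted independently (one multivariate solve); returns
    ``(weights, intercepts)`` with ``weights`` of shape (k, n_proteins).
    Solved by a numerically stable orthogonal decomposition (``lstsq``).
    """
    if Z.barcodes != Y.barcodes:
        raise AlignmentError("reduced GEX and CLR-ADT barcodes are not aligned")
    n_cells, k = Z.values.shape
    if n_cells < k + 1:
        raise FitError(
            f"underdetermined regression: {n_cells} cells for {k} components + intercept"
        )
    design = np.hstack([Z.values, np.ones((n_cells, 1))])
    coef, *_ = np.linalg.lstsq(design, Y.values, rcond=None)
    return coef[:-1], coef[-1]


def fit_pipeline(
    gex: CountMatrix, adt: CountMatrix, cfg: PipelineConfig | None = None
) -> TrainedPipeline:
    """Train the full pipeline on paired GEX/ADT counts.

    Cells are intersected by barcode (GEX order). GEX is size-factor
    normalized and log1p-transformed, reduced by TSVD and z-scored per
    cell; ADT is CLR-transformed; the regression maps one to the other.
    """
    cfg = cfg or PipelineConfig()
    shared = [b for b in gex.barcodes if b in set(adt.barcodes)]
    if not shared:
        raise AlignmentError("GEX and ADT share no barcodes")
    gex_idx = {b: i for i, b in enumerate(gex.barcodes)}
    adt_idx = {b: i for i, b in enumerate(adt.barcodes)}
    gex = gex.subset_cells([gex_idx[b] for b in shared])
    adt = adt.subset_cells([adt_idx[b] for b in shared])

    k_max = min(gex.n_cells - 1, gex.n_features)
    k = cfg.n_components
    clamped_from = None
    if k > k_max:
        if not cfg.clamp_components:
            raise FitError(
                f"n_components={k} exceeds min(cells-1, genes)={k_max} "
                f"and clamping is disabled"
            )
        logger.warning("clamping n_components from %d to %d (data size)", k, k_max)
        clamped_from, k = k, k_max

    norm = normalize_gex(gex)
    loadings, low_dim = fit_tsvd(norm, k, cfg.random_seed)
    z = zscore_cells(low_dim, cfg.zscore_ddof)
    clr = clr_transform(adt, cfg.clr_margin)
    weights, intercepts = fit_linear(z, clr)

    normalization_config = {
        "gex_normalization": "library_median_size_factor_log1p",
        "size_factor_cohort": "input",
        "clr_margin": cfg.clr_margin,
        "zscore_ddof": cfg.zscore_ddof,
        "min_gene_overlap_fraction": cfg.min_gene_overlap_fraction,
        "clamped_from": clamped_from,
        "random_seed": cfg.random_seed,
    }
    return TrainedPipeline(
        gene_names=list(gex.feature_names),
        loadings=loadings,
        weights=weights,
        intercepts=intercepts,
        protein_names=list(adt.feature_names),
        n_components=k,
        normalization_config=normalization_config,
    )


def align_genes(
    p: TrainedPipeline, input_gene_names, min_overlap: float | None = None
) -> AlignmentPlan:
    """Map input gene columns onto the pipeline's trained gene universe.

    Genes present in both map by name; trained genes missing from the input
    are zero-filled downstream; unknown input genes are dropped. An overlap
    fraction below the configured minimum is an error rather than a silent
    low-quality prediction.
    """
    input_gene_names = list(input_gene_names)
    if not input_gene_names:
        raise AlignmentError("input gene list is empty")
    if min_overlap is None:
        min_overlap = float(
            p.normalization_config.get("min_gene_overlap_fraction", 0.3)
        )
    pos = {name: i for i, name in enumerate(input_gene_names)}
    trained_to_input = np.array(
        [pos.get(name, -1) for name in p.gene_names], dtype=np.int64
    )
    missing = [g for g, j in zip(p.gene_names, trained_to_input) if j < 0]
    trained_set = set(p.gene_names)
    dropped = [g for g in input_gene_names if g not in trained_set]
    overlap = 1.0 - len(missing) / len(p.gene_names)
    if overlap < min_overlap:
        raise AlignmentError(
            f"only {overlap:.1%} of trained genes found in input "
            f"(minimum {min_overlap:.1%})"
        )
    if missing:
        logger.warning(
            "%d of %d trained genes absent from input; zero-filling",
            len(missing),
            len(p.gene_names),
        )
    return AlignmentPlan(
        trained_to_input=trained_to_input,
        missing_genes=missing,
        dropped_input_genes=dropped,
        overlap_fraction=overlap,
    )


def _aligned_matrix(p: TrainedPipeline, norm: NormalizedGEX) -> np.ndarray:
    plan = align_genes(p, norm.gene_names)
    X = np.zeros((norm.values.shape[0], len(p.gene_names)))
    present = plan.trained_to_input >= 0
    X[:, present] = norm.values[:, plan.trained_to_input[present]]
    return X


def predict_adt(p: TrainedPipeline, gex) -> PredictedADT:
    """Apply a trained pipeline to a GEX matrix.

    Raw counts (:class:`~adtpred.io.CountMatrix`) are normalized with the
    pipeline's stored settings first (size-factor medians come from the
    input cohort); an already-normalized :class:`NormalizedGEX` is used as
    is. Prediction is ``zscore(X_aligned @ loadings) @ weights + intercepts``.
    """
    if isinstance(gex, CountMatrix):
        norm = normalize_gex(gex)
    elif isinstance(gex, NormalizedGEX):
        norm = gex
    else:
        raise TypeError(f"expected CountMatrix or NormalizedGEX, got {type(gex)}")
    X = _aligned_matrix(p, norm)
    low_dim = X @ p.loadings
    z = zscore_rows(low_dim, p.normalization_config.get("zscore_ddof", "population"))
    values = z @ p.weights + p.intercepts
    return PredictedADT(
        values=values,
        protein_names=list(p.protein_names),
        barcodes=list(norm.barcodes),
    )
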