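"""Closed-form feature importance for the linear prediction pipeline.

Because the pipeline is a composition of three maps — TSVD projection,
cell-wise z-score, linear regression — the Jacobian of predicted ADT with
respect to input GEX features factorizes as the product of the three
component Jacobians. The TSVD Jacobian is the right-singular-vector
(loading) matrix and the regression Jacobian is the weight matrix; only
the z-score Jacobian depends on the cell being evaluated, and it has the
closed form

    J_ij = (1/sigma) * (delta_ij - 1/k - z_i * z_j / k)        (population sd)
    J_ij = (1/sigma) * (delta_ij - 1/k - z_i * z_j / (k - 1))  (sample sd)

with z the standardized reduced vector. The resulting proteins x genes
matrix holds the partial derivative of each predicted protein with respect
to each input gene — a direct, model-exact measure of which genes drive
each protein's prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from ._errors import FitError
from .io import TrainedPipeline
from .predictor import NormalizedGEX, _aligned_matrix, zscore_rows

Aggregation = Literal["per_cell", "mean_over_cells", "at_reference_cell"]


@dataclass
class FeatureImportanceMatrix:
    """Partial derivatives of predicted proteins w.r.t. input genes.

    ``values`` is (proteins x genes) for the aggregated modes and
    (cells x proteins x genes) when ``aggregation == "per_cell"``.
    """

    values: np.ndarray
    protein_names: list[str]
    gene_names: list[str]
    aggregation: Aggregation
    n_cells_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (len(self.protein_names), len(self.gene_names))
        if self.values.shape[-2:] != expected:
            raise ValueError(
                f"importance shape {self.values.shape} does not end in {expected}"
            )


def zscore_jacobian(x, ddof: str = "population") -> np.ndarray:
    """k x k Jacobian of the z-score map at the point ``x``.

    Shift invariance of standardization forces ``J @ 1 = 0`` and scale
    invariance makes the map homogeneous of degree -1 (``J(c*x) = J(x)/c``).
    A constant vector has sigma = 0 and no derivative.
    """
    x = np.asarray(x, dtype=np.float64)
    k = x.shape[0]
    if k < 2:
        raise FitError("z-score Jacobian needs at least 2 components")
    nddof = 0 if ddof == "population" else 1
    mu = x.mean()
    sigma = x.std(ddof=nddof)
    if sigma == 0:
        raise FitError("z-score Jacobian is undefined for a constant vector")
    z = (x - mu) / sigma
    denom = k if ddof == "population" else k - 1
    return (np.eye(k) - 1.0 / k - np.outer(z, z) / denom) / sigma


def feature_importance(
    p: TrainedPipeline,
    gex_cells: NormalizedGEX,
    aggregation: Aggregation = "mean_over_cells",
) -> FeatureImportanceMatrix:
    """Jacobian of predicted ADT w.r.t. input genes, evaluated on given cells.

    Per cell ``c`` with reduced vector ``x_c``, the full Jacobian is
    ``loadings @ J_z(x_c) @ weights``, reported transposed as proteins x
    genes. ``mean_over_cells`` (default) averages over the provided cells;
    ``at_reference_cell`` evaluates once at the mean reduced vector;
    ``per_cell`` returns the full per-cell stack.
    """
    if gex_cells.values.shape[0] == 0:
        raise ValueError("feature_importance needs at least one cell")
    ddof = p.normalization_config.get("zscore_ddof", "population")
    X = _aligned_matrix(p, gex_cells)
    low_dim = X @ p.loadings  # cells x k

    def cell_jacobian(x_c: np.ndarray) -> np.ndarray:
        # (loadings @ J_z @ weights).T  ->  proteins x genes
        inner = zscore_jacobian(x_c, ddof) @ p.weights  # k x proteins
        return (p.loadings @ inner).T

    if aggregation == "at_reference_cell":
        values = cell_jacobian(low_dim.mean(axis=0))
    elif aggregation == "mean_over_cells":
        acc = np.zeros((len(p.protein_names), len(p.gene_names)))
        for x_c in low_dim:
            acc += cell_jacobian(x_c)
        values = acc / low_dim.shape[0]
    elif aggregation == "per_cell":
        values = np.stack([cell_jacobian(x_c) for x_c in low_dim])
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return FeatureImportanceMatrix(
        values=values,
        protein_names=list(p.protein_names),
        gene_names=list(p.gene_names),
        aggregation=aggregation,
        n_cells_used=low_dim.shape[0],
    )


def top_features(
    fi: FeatureImportanceMatrix, protein: str, n: int = 10
) -> pd.DataFrame:
    """Rank genes driving one protein's prediction by |importance|.

    Returns a DataFrame with columns ``gene`` and ``importance`` (signed),
    sorted by descending magnitude; ties break lexicographically by gene
    name, so the ranking is stable across runs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fi.aggregation == "per_cell":
        raise ValueError("rank an aggregated importance matrix, not per_cell")
    try:
        row = fi.values[fi.protein_names.index(protein)]
    except ValueError:
        raise KeyError(
            f"unknown protein {protein!r}; available: {fi.protein_names}"
        ) from None
    order = sorted(
        range(len(fi.gene_names)),
        key=lambda i: (-abs(row[i]), fi.gene_names[i]),
    )[:n]
    return pd.DataFrame(
        {
            "gene": [fi.gene_names[i] for i in order],
            "importance": [row[i] for i in order],
        }
    )


def importance_to_csv(fi: FeatureImportanceMatrix, path) -> Path:
    """Write a proteins x genes importance matrix as CSV."""
    if fi.aggregation == "per_cell":
        raise ValueError("export an aggregated importance matrix, not per_cell")
    path = Path(path)
    pd.DataFrame(fi.values, index=fi.protein_names, columns=fi.gene_names).to_csv(path)
    return path


def importance_to_long_tsv(fi: FeatureImportanceMatrix, path) -> Path:
    """Write long-format (protein, gene, importance) TSV for downstream tools."""
    if fi.aggregation == "per_cell":
        raise ValueError("export an aggregated importance matrix, not per_cell")
    path = Path(path)
    df = (
        pd.DataFrame(fi.values, index=fi.protein_names, columns=fi.gene_names)
        .rename_axis("protein")
        .reset_index()
        .melt(id_vars="protein", var_name="gene", value_name="importance")
    )
    df.to_csv(path, sep="\t", index=False)
    return path
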