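"""Accuracy metrics and the dropout-robustness simulation.

Prediction accuracy is summarized as the overall RMSE plus Pearson
correlations computed two ways: per protein (across cells, as in held-out
benchmark evaluations) and per cell (across proteins). Robustness is
probed by iteratively thinning the GEX count matrix — each round
independently zeroes every currently non-zero entry with probability
``p_zero`` — re-running the full prediction path on the degraded counts,
and tracking per-cell correlation until the dropout rate exceeds a stop
threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import AlignmentError
from .io import CountMatrix, TrainedPipeline
from .predictor import PredictedADT, predict_adt
from .preprocess import CLRMatrix, NormalizedGEX


def _check_aligned(pred: PredictedADT, truth: CLRMatrix) -> None:
    if pred.protein_names != truth.protein_names:
        raise AlignmentError("prediction and truth protein names differ")
    if pred.barcodes != truth.barcodes:
        raise AlignmentError("prediction and truth barcodes differ")


def rmse(pred: PredictedADT, truth: CLRMatrix) -> float:
    """Root mean squared error over all cells x proteins."""
    _check_aligned(pred, truth)
    return float(np.sqrt(np.mean((pred.values - truth.values) ** 2)))


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between two equally shaped matrices.

    Rows where either vector is constant get NaN (correlation undefined);
    callers must treat NaN as an explicit undefined flag and exclude it
    from summaries, never propagate it.
    """
    if a.shape != b.shape:
        raise AlignmentError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.shape[1] < 2:
        raise ValueError("Pearson correlation needs at least 2 paired observations")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", ac, bc) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def pearson_per_protein(pred: PredictedADT, truth: CLRMatrix) -> pd.Series:
    """Pearson r per protein across cells; NaN flags an undefined correlation."""
    _check_aligned(pred, truth)
    r = _pearson_rows(pred.values.T, truth.values.T)
    return pd.Series(r, index=pred.protein_names, name="pearson_r")


def pearson_per_cell(pred: PredictedADT, truth: CLRMatrix) -> pd.Series:
    """Pearson r per cell across proteins; NaN flags an undefined correlation."""
    _check_aligned(pred, truth)
    r = _pearson_rows(pred.values, truth.values)
    return pd.Series(r, index=pred.barcodes, name="pearson_r")


@dataclass
class EvaluationReport:
    """RMSE plus per-protein and per-cell Pearson correlations."""

    rmse_overall: float
    pearson_per_protein: pd.Series
    pearson_per_cell: pd.Series

    @property
    def summary(self) -> dict:
        pp = self.pearson_per_protein
        pc = self.pearson_per_cell
        return {
            "rmse": self.rmse_overall,
            "median_pearson_per_protein": float(np.nanmedian(pp)) if pp.notna().any() else None,
            "median_pearson_per_cell": float(np.nanmedian(pc)) if pc.notna().any() else None,
            "per_cell_iqr": (
                [float(np.nanpercentile(pc, 25)), float(np.nanpercentile(pc, 75))]
                if pc.notna().any()
                else None
            ),
            "n_undefined_per_protein": int(pp.isna().sum()),
            "n_undefined_per_cell": int(pc.isna().sum()),
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = dict(self.summary)
        payload["pearson_per_protein"] = {
            k: (None if np.isnan(v) else float(v))
            for k, v in self.pearson_per_protein.items()
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def to_csv(self, path_per_protein, path_per_cell) -> None:
        self.pearson_per_protein.rename_axis("protein").to_csv(path_per_protein)
        self.pearson_per_cell.rename_axis("barcode").to_csv(path_per_cell)


def evaluate(pred: PredictedADT, truth: CLRMatrix) -> EvaluationReport:
    """Compute the full accuracy report for a prediction against measured CLR-ADT."""
    return EvaluationReport(
        rmse_overall=rmse(pred, truth),
        pearson_per_protein=pearson_per_protein(pred, truth),
        pearson_per_cell=pearson_per_cell(pred, truth),
    )


@dataclass
class DropoutCurve:
    """Per-iteration record of the dropout-robustness simulation.

    ``iterations`` holds one dict per iteration with the realized dropout
    rate (zero fraction of the whole GEX matrix, originally zero entries
    included) and the per-cell Pearson summary; iteration 0 is the
    untouched input.
    """

    iterations: list[dict]
    p_zero: float
    stop_dropout: float
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.iterations)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "p_zero": self.p_zero,
                    "stop_dropout": self.stop_dropout,
                    "seed": self.seed,
                    "dropout_definition": "zeros / total entries of the GEX matrix",
                    "iterations": self.iterations,
                },
                indent=2,
            )
        )
        return path


def _normalize_degraded(counts: np.ndarray, gene_names, barcodes) -> NormalizedGEX:
    """Library-size normalization tolerating zero-total cells.

    Cells thinned to zero total counts are retained with an all-zero
    normalized vector rather than dropped; their correlations come out
    undefined downstream.
    """
    total = counts.sum(axis=1).astype(np.float64)
    positive = total > 0
    if not positive.any():
        sf = np.ones_like(total)
    else:
        sf = total / np.median(total[positive])
    safe_sf = np.where(sf > 0, sf, 1.0)
    values = np.log1p(counts / safe_sf[:, None])
    values[~positive] = 0.0
    return NormalizedGEX(
        values=values,
        gene_names=list(gene_names),
        barcodes=list(barcodes),
        size_factors=safe_sf,
    )


def dropout_simulation(
    gex: CountMatrix,
    adt_truth: CLRMatrix,
    p: TrainedPipeline,
    p_zero: float = 0.10,
    stop_dropout: float = 0.99,
    seed: int = 0,
    max_iterations: int = 10_000,
) -> DropoutCurve:
    """Iteratively thin the GEX counts and track prediction quality.

    Each iteration flags every currently non-zero entry independently with
    probability ``p_zero`` (a Bernoulli draw), zeroes the flagged entries,
    re-normalizes the degraded counts, re-predicts ADT and records the
    per-cell Pearson summary. The loop stops once the realized dropout
    rate (zero fraction over the whole matrix) exceeds ``stop_dropout``.
    """
    if not (0 < p_zero <= 1):
        raise ValueError("p_zero must be in (0, 1]")
    if gex.values.size == 0 or not (gex.values > 0).any():
        raise ValueError("dropout simulation needs a GEX matrix with non-zero entries")
    if gex.barcodes != adt_truth.barcodes:
        raise AlignmentError("GEX and ADT-truth barcodes differ")

    rng = np.random.default_rng(seed)
    counts = gex.values.astype(np.int64).copy()
    total_entries = counts.size

    def record(iteration: int) -> dict:
        norm = _normalize_degraded(counts, gex.feature_names, gex.barcodes)
        pred = predict_adt(p, norm)
        r = _pearson_rows(pred.values, adt_truth.values)
        defined = r[~np.isnan(r)]
        rate = 1.0 - np.count_nonzero(counts) / total_entries
        return {
            "iteration": iteration,
            "realized_dropout_rate": float(rate),
            "n_nonzero": int(np.count_nonzero(counts)),
            "median_pearson_per_cell": float(np.median(defined)) if defined.size else None,
            "q25": float(np.percentile(defined, 25)) if defined.size else None,
            "q75": float(np.percentile(defined, 75)) if defined.size else None,
            "n_undefined": int(np.isnan(r).sum()),
        }

    iterations = [record(0)]
    it = 0
    while (
        iterations[-1]["realized_dropout_rate"] <= stop_dropout
        and iterations[-1]["n_nonzero"] > 0
    ):
        it += 1
        if it > max_iterations:
            raise RuntimeError(
                f"dropout simulation did not reach {stop_dropout} in {max_iterations} iterations"
            )
        nz = counts > 0
        flags = rng.random(counts.shape) < p_zero
        counts[nz & flags] = 0
        iterations.append(record(it))
    return DropoutCurve(
        iterations=iterations, p_zero=p_zero, stop_dropout=stop_dropout, seed=seed
    )
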