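"""Per-cell quality control and normalization.

QC follows the standard scater-style recipe: three per-cell metrics
(total counts, detected features, percent mitochondrial counts) filtered
by a scaled-MAD outlier rule (default 3 MADs; the mitochondrial metric is
thresholded on the upper side only). GEX counts are normalized by
per-cell size factors then log1p-transformed; ADT counts get the Seurat
log1p dialect of the centered log-ratio (CLR) transformation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._errors import NormalizationError, QCError
from .io import CountMatrix

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass
class QCConfig:
    """Settings for per-cell quality control.

    ``nmads`` is the outlier threshold in scaled-MAD units; ``mito_pattern``
    is a case-insensitive prefix regex matched against feature names
    (default catches human "MT-" and mouse "mt-"); counts/features metrics
    are tested on the log1p scale when ``log_transform_counts_metrics``.
    """

    nmads: float = 3.0
    mito_pattern: str = "MT-"
    log_transform_counts_metrics: bool = True

    def __post_init__(self) -> None:
        if self.nmads <= 0:
            raise ValueError("nmads must be positive")


@dataclass
class NormalizedGEX:
    """log1p(size-factor-scaled UMI counts), cells x genes."""

    values: np.ndarray
    gene_names: list[str]
    barcodes: list[str]
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.size_factors = np.asarray(self.size_factors, dtype=np.float64)


@dataclass
class CLRMatrix:
    """Centered log-ratio transformed ADT values, cells x proteins."""

    values: np.ndarray
    protein_names: list[str]
    barcodes: list[str]
    margin: Literal["across_cells", "within_cell"] = "across_cells"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def compute_qc_metrics(m: CountMatrix, cfg: QCConfig | None = None) -> pd.DataFrame:
    """Per-cell QC metrics: ``total_counts``, ``n_features``, ``pct_mito``.

    ``pct_mito`` is the percentage of counts in features whose name matches
    ``cfg.mito_pattern`` (case-insensitive prefix match); it is defined as 0
    for cells with zero total counts and when no feature matches.
    """
    cfg = cfg or QCConfig()
    counts = m.values
    total = counts.sum(axis=1).astype(np.float64)
    n_features = (counts > 0).sum(axis=1)
    pattern = re.compile(cfg.mito_pattern, re.IGNORECASE)
    mito_mask = np.array([bool(pattern.match(name)) for name in m.feature_names])
    mito_total = counts[:, mito_mask].sum(axis=1) if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, 100.0 * mito_total / np.maximum(total, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "total_counts": total,
            "n_features": n_features.astype(np.int64),
            "pct_mito": pct_mito,
        },
        index=pd.Index(m.barcodes, name="barcode"),
    )


def mad_outlier_mask(
    values, nmads: float = 3.0, sides: Literal["upper", "both"] = "both"
) -> np.ndarray:
    """Boolean keep-mask flagging values within ``nmads`` scaled MADs of the median.

    The MAD is scaled by 1.4826 for consistency with the normal distribution.
    With a zero MAD (constant or majority-constant input), "both" keeps only
    values equal to the median and "upper" keeps values <= median.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("mad_outlier_mask requires at least one value")
    med = np.median(x)
    smad = MAD_SCALE * np.median(np.abs(x - med))
    if sides == "upper":
        return x <= med + nmads * smad
    if sides == "both":
        return (x >= med - nmads * smad) & (x <= med + nmads * smad)
    raise ValueError(f"sides must be 'upper' or 'both', got {sides!r}")


def qc_filter(m: CountMatrix, cfg: QCConfig | None = None):
    """Remove outlier cells; returns ``(filtered CountMatrix, report dict)``.

    A cell is kept iff it passes all three metric masks. Counts and detected
    features are tested two-sided (on the log1p scale by default); percent
    mitochondrial counts is tested on the raw scale, upper side only.
    Thresholds are computed once on the full input, so the filter is
    idempotent on its own output under frozen thresholds.
    """
    cfg = cfg or QCConfig()
    metrics = compute_qc_metrics(m, cfg)

    masks = {}
    thresholds = {}
    for name, sides in (("total_counts", "both"), ("n_features", "both")):
        vals = metrics[name].to_numpy(dtype=np.float64)
        scale = "log1p" if cfg.log_transform_counts_metrics else "raw"
        tested = np.log1p(vals) if scale == "log1p" else vals
        med = np.median(tested)
        smad = MAD_SCALE * np.median(np.abs(tested - med))
        masks[name] = mad_outlier_mask(tested, cfg.nmads, sides)
        thresholds[name] = {
            "scale": scale,
            "lower": med - cfg.nmads * smad,
            "upper": med + cfg.nmads * smad,
            "sides": sides,
        }
    pm = metrics["pct_mito"].to_numpy(dtype=np.float64)
    med = np.median(pm)
    smad = MAD_SCALE * np.median(np.abs(pm - med))
    masks["pct_mito"] = mad_outlier_mask(pm, cfg.nmads, "upper")
    thresholds["pct_mito"] = {
        "scale": "raw",
        "upper": med + cfg.nmads * smad,
        "sides": "upper",
    }

    keep = masks["total_counts"] & masks["n_features"] & masks["pct_mito"]
    if not keep.any():
        raise QCError(
            "QC removed every cell; review nmads/mito_pattern thresholds"
        )
    report = {
        "n_cells_in": int(m.n_cells),
        "n_cells_kept": int(keep.sum()),
        "n_removed_total": int((~keep).sum()),
        "removed_by_metric": {k: int((~v).sum()) for k, v in masks.items()},
        "thresholds": thresholds,
        "nmads": cfg.nmads,
    }
    return m.subset_cells(keep), report


def default_size_factors(m: CountMatrix) -> np.ndarray:
    """Library-size factors: per-cell total counts over the median total.

    The median is taken over cells with nonzero totals. Cells with zero
    total counts have no defined default factor and raise.
    """
    total = m.values.sum(axis=1).astype(np.float64)
    zero = total == 0
    if zero.any():
        bad = [m.barcodes[i] for i in np.flatnonzero(zero)[:10]]
        raise NormalizationError(
            f"{int(zero.sum())} cell(s) have zero total counts and no default "
            f"size factor (e.g. {bad}); provide size_factors explicitly"
        )
    return total / np.median(total)


def normalize_gex(m: CountMatrix, size_factors=None) -> NormalizedGEX:
    """log1p(counts / size_factor) per cell.

    Default size factors are library-size/median scaling; externally
    computed factors (e.g. scran pooled deconvolution) can be injected.
    """
    if m.modality != "GEX":
        raise NormalizationError(f"normalize_gex expects GEX counts, got {m.modality}")
    if size_factors is None:
        sf = default_size_factors(m)
    else:
        sf = np.asarray(size_factors, dtype=np.float64)
        if sf.shape != (m.n_cells,):
            raise NormalizationError(
                f"size_factors must have one entry per cell ({m.n_cells}), got {sf.shape}"
            )
        if np.any(sf <= 0):
            raise NormalizationError("size_factors must all be positive")
    values = np.log1p(m.values / sf[:, None])
    return NormalizedGEX(
        values=values,
        gene_names=list(m.feature_names),
        barcodes=list(m.barcodes),
        size_factors=sf,
    )


def clr_transform(
    m: CountMatrix, margin: Literal["across_cells", "within_cell"] = "across_cells"
) -> CLRMatrix:
    """Centered log-ratio transform in the log1p dialect (as in Seurat):

        clr(x)_i = log1p( x_i / exp(mean_j log1p(x_j)) )

    With ``margin="across_cells"`` (default) each protein is centered over
    cells; ``"within_cell"`` centers each cell's vector over proteins.
    Zero counts map to finite values (log1p(0) = 0).
    """
    if m.modality != "ADT":
        raise NormalizationError(f"clr_transform expects ADT counts, got {m.modality}")
    if m.values.size == 0:
        raise NormalizationError("clr_transform on an empty matrix")
    x = m.values.astype(np.float64)
    axis = 0 if margin == "across_cells" else 1
    if margin not in ("across_cells", "within_cell"):
        raise ValueError(f"unknown margin {margin!r}")
    geo = np.exp(np.mean(np.log1p(x), axis=axis, keepdims=True))
    values = np.log1p(x / geo)
    return CLRMatrix(
        values=values,
        protein_names=list(m.feature_names),
        barcodes=list(m.barcodes),
        margin=margin,
    )
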