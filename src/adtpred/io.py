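"""Reading and writing count matrices and trained-pipeline files.

Count matrices travel as MatrixMarket triplets (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, optionally gzipped) following the 10x
convention of features-by-cells on disk, or as small dense CSV files
(cells in rows). Trained pipelines are stored in a single ``.npz``
container holding the float64 arrays verbatim plus a JSON metadata block,
which makes the round trip bit-exact.
"""

from __future__ import annotations

import gzip
import io as _stdio
import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._errors import (
    MatrixFormatError,
    MatrixValidationError,
    ModelFormatError,
    ModelVersionError,
)

PIPELINE_FORMAT_VERSION = "1"

#: Matrices with 2**31 or more stored entries are outside the tested envelope
#: (MatrixMarket indices and the dense in-memory representation both assume
#: 32-bit-addressable triplet counts here).
MAX_TESTED_ENTRIES = 2**31 - 1


def _dedup_names(names: Sequence[str]) -> list[str]:
    """Make names unique by appending '.1', '.2', ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name not in seen:
            seen[name] = 0
            out.append(name)
        else:
            seen[name] += 1
            candidate = f"{name}.{seen[name]}"
            while candidate in seen:
                seen[name] += 1
                candidate = f"{name}.{seen[name]}"
            seen[candidate] = 0
            out.append(candidate)
    return out


@dataclass
class CountMatrix:
    """Cells-by-features matrix of non-negative integer UMI counts.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_features)`` integer array.
    feature_names
        Unique feature names, one per column (de-duplicated on load).
    barcodes
        Unique cell barcodes, one per row.
    modality
        Either ``"GEX"`` or ``"ADT"``.
    raw_feature_names
        Original on-disk names before de-duplication, when they differed.
    """

    values: np.ndarray
    feature_names: list[str]
    barcodes: list[str]
    modality: str
    raw_feature_names: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values)
        self.feature_names = list(self.feature_names)
        self.barcodes = list(self.barcodes)
        if self.modality not in ("GEX", "ADT"):
            raise MatrixValidationError(
                f"modality must be 'GEX' or 'ADT', got {self.modality!r}"
            )
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D matrix")
        n_cells, n_features = self.values.shape
        if len(self.feature_names) != n_features:
            raise MatrixValidationError(
                f"{len(self.feature_names)} feature names for {n_features} columns"
            )
        if len(self.barcodes) != n_cells:
            raise MatrixValidationError(
                f"{len(self.barcodes)} barcodes for {n_cells} rows"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise MatrixValidationError("barcodes are not unique")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise MatrixValidationError("feature names are not unique")
        if self.values.size:
            if np.issubdtype(self.values.dtype, np.floating):
                if not np.all(self.values == np.floor(self.values)):
                    raise MatrixValidationError("counts must be integral")
                self.values = self.values.astype(np.int64)
            if self.values.min() < 0:
                raise MatrixValidationError("counts must be non-negative")
        self.values = self.values.astype(np.int64, copy=False)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            values=self.values[idx],
            barcodes=[self.barcodes[i] for i in idx],
            raw_feature_names=self.raw_feature_names,
        )

    def subset_features(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            raw_feature_names=None,
        )


@dataclass
class TrainedPipeline:
    """Frozen trained prediction pipeline.

    Holds the three fitted components — the TSVD loading matrix, the
    regression weights and intercepts — together with the ordered training
    gene universe and protein names needed to align new data.
    """

    gene_names: list[str]
    loadings: np.ndarray  # genes x k, right singular vectors
    weights: np.ndarray  # k x proteins
    intercepts: np.ndarray  # proteins
    protein_names: list[str]
    n_components: int
    normalization_config: dict
    format_version: str = PIPELINE_FORMAT_VERSION

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.intercepts = np.asarray(self.intercepts, dtype=np.float64)
        self.gene_names = list(self.gene_names)
        self.protein_names = list(self.protein_names)
        if self.loadings.shape[0] != len(self.gene_names):
            raise ModelFormatError("loadings rows must match gene_names length")
        if self.loadings.shape[1] != self.n_components:
            raise ModelFormatError("loadings columns must equal n_components")
        if self.weights.shape[0] != self.n_components:
            raise ModelFormatError("weights rows must equal n_components")
        if self.weights.shape[1] != len(self.protein_names):
            raise ModelFormatError("weights columns must match protein_names")
        if self.intercepts.shape != (len(self.protein_names),):
            raise ModelFormatError("intercepts length must match protein_names")


def _open_maybe_gzip(path: Path, mode: str = "rb"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_mtx_triplet(
    matrix_path,
    features_path,
    barcodes_path,
    modality: str,
    *,
    orientation: str = "features_by_cells",
) -> CountMatrix:
    """Read a 10x-style MTX triplet into a cells-by-features :class:`CountMatrix`.

    The on-disk matrix is assumed features-by-cells (the 10x convention) and
    transposed on load; pass ``orientation="cells_by_features"`` for files
    already stored cells-first. The features file may have 1-3 tab-separated
    columns (id / id+symbol / id+symbol+type); the symbol column is used as
    the feature name when present.
    """
    matrix_path, features_path, barcodes_path = (
        Path(matrix_path),
        Path(features_path),
        Path(barcodes_path),
    )
    if orientation not in ("features_by_cells", "cells_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        with _open_maybe_gzip(matrix_path) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise MatrixFormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)

    feat_df = _read_lines_tsv(features_path)
    bc_df = _read_lines_tsv(barcodes_path)
    raw_features = (
        list(feat_df[1] if feat_df.shape[1] >= 2 else feat_df[0])
        if not feat_df.empty
        else []
    )
    barcodes = list(bc_df[0]) if not bc_df.empty else []

    if orientation == "features_by_cells":
        n_feat_disk, n_cell_disk = mat.shape
        mat = mat.T
    else:
        n_cell_disk, n_feat_disk = mat.shape
    if len(raw_features) != n_feat_disk:
        raise MatrixFormatError(
            f"features file {features_path} has {len(raw_features)} records "
            f"but the matrix header declares {n_feat_disk} features"
        )
    if len(barcodes) != n_cell_disk:
        raise MatrixFormatError(
            f"barcodes file {barcodes_path} has {len(barcodes)} records "
            f"but the matrix header declares {n_cell_disk} cells"
        )

    data = mat.data
    if data.size and np.issubdtype(data.dtype, np.floating):
        if not np.all(data == np.floor(data)):
            raise MatrixValidationError(f"{matrix_path} contains non-integer entries")
    if data.size and data.min() < 0:
        raise MatrixValidationError(f"{matrix_path} contains negative entries")

    names = _dedup_names(raw_features)
    return CountMatrix(
        values=np.asarray(mat.todense()),
        feature_names=names,
        barcodes=barcodes,
        modality=modality,
        raw_feature_names=raw_features if names != raw_features else None,
    )


def write_mtx_triplet(m: CountMatrix, out_dir) -> dict[str, Path]:
    """Write ``m`` as matrix.mtx / features.tsv / barcodes.tsv under ``out_dir``.

    The matrix is stored features-by-cells (10x convention), so
    :func:`read_mtx_triplet` round-trips it exactly.
    """
    if m.values.size >= MAX_TESTED_ENTRIES:
        raise MatrixValidationError(
            f"matrices with >= 2^31 entries are outside the tested envelope "
            f"(got {m.values.size})"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(m.values.T), field="integer")
    names = m.raw_feature_names if m.raw_feature_names is not None else m.feature_names
    paths["features"].write_text("".join(f"{n}\n" for n in names))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in m.barcodes))
    return paths


def read_dense_csv(path, modality: str) -> CountMatrix:
    """Read a dense CSV (header = feature names, first column = barcodes)."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        values=df.to_numpy(),
        feature_names=_dedup_names([str(c) for c in df.columns]),
        barcodes=[str(b) for b in df.index],
        modality=modality,
    )


def write_dense_csv(m: CountMatrix, path) -> Path:
    path = Path(path)
    pd.DataFrame(m.values, index=m.barcodes, columns=m.feature_names).to_csv(path)
    return path


def save_pipeline(p: TrainedPipeline, path) -> None:
    """Serialize a trained pipeline to a single ``.npz`` container.

    Arrays are stored as raw float64, so :func:`load_pipeline` restores them
    bit-exactly; names, configuration and the format version live in a JSON
    metadata entry.
    """
    meta = {
        "format_version": p.format_version,
        "gene_names": p.gene_names,
        "protein_names": p.protein_names,
        "n_components": p.n_components,
        "normalization_config": p.normalization_config,
    }
    path = Path(path)
    with open(path, "wb") as fh:
        np.savez(
            fh,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            loadings=p.loadings,
            weights=p.weights,
            intercepts=p.intercepts,
        )


def load_pipeline(path) -> TrainedPipeline:
    """Load a pipeline saved by :func:`save_pipeline`, checking the format version."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as archive:
            sections = {"meta", "loadings", "weights", "intercepts"}
            missing = sections - set(archive.files)
            if missing:
                raise ModelFormatError(
                    f"model file {path} is missing section(s): {sorted(missing)}"
                )
            meta = json.loads(bytes(archive["meta"]).decode())
            loadings = archive["loadings"]
            weights = archive["weights"]
            intercepts = archive["intercepts"]
    except (zipfile.BadZipFile, OSError, ValueError, _stdio.UnsupportedOperation) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != PIPELINE_FORMAT_VERSION:
        raise ModelVersionError(
            f"model file {path} has format_version {version!r}; "
            f"this package reads version {PIPELINE_FORMAT_VERSION!r}"
        )
    return TrainedPipeline(
        gene_names=meta["gene_names"],
        loadings=loadings,
        weights=weights,
        intercepts=intercepts,
        protein_names=meta["protein_names"],
        n_components=meta["n_components"],
        normalization_config=meta["normalization_config"],
        format_version=version,
    )
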