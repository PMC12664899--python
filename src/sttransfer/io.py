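"""Annotated expression containers and gene alignment.

The pipeline works with two modalities: an annotated single-cell reference
(counts + cell-type labels) and a spatial dataset (counts + 2-D
coordinates). Both are carried as :class:`ExpressionDataset`, a thin
validated wrapper convertible to/from :class:`anndata.AnnData` with the
community conventions (coordinates in ``obsm["spatial"]``, labels in an
``obs`` column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_LABEL_KEY = "cell_type"
MIN_SHARED_GENES = 50


@dataclass
class ExpressionDataset:
    """Cells x genes raw count matrix with optional coordinates and labels.

    Counts stay raw (integers) here; normalization is owned by downstream
    consumers (the count-based VAE in particular).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    coords: np.ndarray | None = None
    labels: pd.Categorical | None = None
    batch: str = "reference"

    def __post_init__(self):
        if sp.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (self.counts < 0).any():
            raise ValueError("counts contain negative entries")
        if np.isnan(self.counts.astype(float)).any():
            raise ValueError("counts contain NaNs")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, d = self.counts.shape
        if len(self.gene_ids) != d:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {d} columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise ValueError(f"coords must be {n} x 2, got {self.coords.shape}")
        if self.labels is not None:
            self.labels = pd.Categorical(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in genes]
        return ExpressionDataset(
            counts=self.counts[:, cols],
            gene_ids=list(genes),
            cell_ids=list(self.cell_ids),
            coords=None if self.coords is None else self.coords.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            batch=self.batch,
        )

    # -- AnnData interop ---------------------------------------------------
    def to_anndata(self, label_key: str = DEFAULT_LABEL_KEY) -> ad.AnnData:
        adata = ad.AnnData(
            X=sp.csr_matrix(self.counts.astype(np.float32)),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        if self.coords is not None:
            adata.obsm["spatial"] = self.coords
        if self.labels is not None:
            adata.obs[label_key] = pd.Categorical(self.labels)
        adata.obs["batch"] = self.batch
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, role: str,
                     label_key: str = DEFAULT_LABEL_KEY) -> "ExpressionDataset":
        X = adata.X
        if sp.issparse(X):
            X = np.asarray(X.todense())
        X = np.asarray(X)
        if not np.allclose(X, np.round(X)):
            raise ValueError("expression matrix does not look like raw counts")
        coords = None
        labels = None
        if role == "spatial":
            if "spatial" not in adata.obsm:
                raise ValueError('spatial dataset lacks the obsm["spatial"] coordinate slot')
            coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
            if label_key in adata.obs:  # optional ground truth for evaluation
                labels = pd.Categorical(adata.obs[label_key])
        elif role == "reference":
            if label_key not in adata.obs:
                raise ValueError(f"reference dataset lacks the label column {label_key!r} in obs")
            labels = pd.Categorical(adata.obs[label_key])
        else:
            raise ValueError(f"role must be 'reference' or 'spatial', got {role!r}")
        return cls(
            counts=np.round(X).astype(np.int64),
            gene_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            coords=coords,
            labels=labels,
            batch=role,
        )

    def write(self, path: str | Path, label_key: str = DEFAULT_LABEL_KEY) -> None:
        self.to_anndata(label_key=label_key).write_h5ad(Path(path))


def read_dataset(path: str | Path, role: str,
                 label_key: str = DEFAULT_LABEL_KEY) -> ExpressionDataset:
    """Read an h5ad file or a CSV directory into a validated dataset.

    The CSV fallback expects a directory with ``counts.csv`` (cells x genes,
    cell ids as index, gene ids as header) and ``metadata.csv`` (cell ids as
    index; ``x``/``y`` columns for spatial data, the label column for
    references).
    """
    path = Path(path)
    if path.is_dir():
        counts = pd.read_csv(path / "counts.csv", index_col=0)
        meta = pd.read_csv(path / "metadata.csv", index_col=0)
        meta = meta.reindex(counts.index)
        coords = None
        labels = None
        if role == "spatial":
            if not {"x", "y"}.issubset(meta.columns):
                raise ValueError("spatial metadata.csv lacks the x/y coordinate columns")
            coords = meta[["x", "y"]].to_numpy(dtype=float)
            if label_key in meta.columns:
                labels = pd.Categorical(meta[label_key])
        elif role == "reference":
            if label_key not in meta.columns:
                raise ValueError(f"reference metadata.csv lacks the label column {label_key!r}")
            labels = pd.Categorical(meta[label_key])
        else:
            raise ValueError(f"role must be 'reference' or 'spatial', got {role!r}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts.csv contains non-numeric entries")
        return ExpressionDataset(
            counts=values.astype(np.int64),
            gene_ids=list(counts.columns),
            cell_ids=[str(i) for i in counts.index],
            coords=coords,
            labels=labels,
            batch=role,
        )
    adata = ad.read_h5ad(path)
    return ExpressionDataset.from_anndata(adata, role=role, label_key=label_key)


def align_genes(ref: ExpressionDataset, spatial: ExpressionDataset,
                case_fold: bool = False, min_shared: int = MIN_SHARED_GENES,
                ) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their shared genes, identically ordered.

    Genes are matched by exact string identity (optionally case-folded).
    Genes with zero counts in one modality are retained: dropping them is a
    normalization decision that belongs downstream.
    """
    if ref.n_cells == 0 or spatial.n_cells == 0:
        raise ValueError("cannot align empty datasets")
    key = (lambda g: g.casefold()) if case_fold else (lambda g: g)
    spatial_keys = {key(g): g for g in spatial.gene_ids}
    shared_ref = [g for g in ref.gene_ids if key(g) in spatial_keys]
    if not shared_ref:
        raise ValueError("reference and spatial datasets share no genes")
    if len(shared_ref) < min_shared:
        logger.warning("only %d shared genes (minimum advised: %d)", len(shared_ref), min_shared)
    if ref.gene_ids == spatial.gene_ids:
        return ref, spatial
    shared_spatial = [spatial_keys[key(g)] for g in shared_ref]
    return ref.subset_genes(shared_ref), spatial.subset_genes(shared_spatial)
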