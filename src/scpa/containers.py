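"""Shared in-memory containers for the pipeline.

All matrices in this package are gene-major (genes x cells / genes x samples)
and label-addressed: positional indices never cross module boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

MITO_PREFIX = "MT-"


@dataclass
class GeneExpressionMatrix:
    """Sparse genes x cells UMI count matrix with cell-level metadata.

    ``cell_meta`` is indexed by barcode and typically carries ``sample``,
    ``group`` and (for synthetic data) ``true_cluster`` columns.
    """

    counts: sp.csr_matrix            # genes x cells, non-negative integers
    gene_ids: np.ndarray             # str array, len = n_genes
    cell_ids: np.ndarray             # str array, len = n_cells
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="barcode"))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def mito_mask(self) -> np.ndarray:
        return np.array([g.startswith(MITO_PREFIX) for g in self.gene_ids])

    def subset_cells(self, keep: np.ndarray) -> "GeneExpressionMatrix":
        """Subset by boolean mask or integer positions (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GeneExpressionMatrix(
            counts=self.counts[:, keep].tocsr(),
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            cell_meta=self.cell_meta.iloc[keep].copy(),
        )

    def subset_genes(self, keep: np.ndarray) -> "GeneExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GeneExpressionMatrix(
            counts=self.counts[keep, :].tocsr(),
            gene_ids=self.gene_ids[keep],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta.copy(),
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())
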