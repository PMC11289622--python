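"""Core container for spot-based spatial expression data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .spatial import TractGeometry

__all__ = ["SpotDataset"]


@dataclass
class SpotDataset:
    """A spot-level UMI count dataset registered to a device tract.

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        Integer UMI counts, genes x spots.
    genes : pandas.Index
        Gene symbols (rows of ``counts``).
    spots : pandas.DataFrame
        Indexed by barcode; columns ``x_um``, ``y_um``, ``in_tissue``,
        ``artifact`` (and optionally the array row/col).
    tract : TractGeometry
        Location of the device tract (or matched naive reference point).
    """

    counts: sp.csr_matrix
    genes: pd.Index
    spots: pd.DataFrame
    tract: TractGeometry

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        if self.counts.shape != (len(self.genes), len(self.spots)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if not self.genes.is_unique:
            raise ValueError("gene names must be unique")
        if not self.spots.index.is_unique:
            raise ValueError("spot barcodes must be unique")
        for col in ("x_um", "y_um"):
            if col not in self.spots.columns:
                raise ValueError(f"spots table missing column {col!r}")
        if "in_tissue" not in self.spots.columns:
            self.spots = self.spots.assign(in_tissue=True)
        if "artifact" not in self.spots.columns:
            self.spots = self.spots.assign(artifact=False)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.spots.index

    def spot_totals(self) -> np.ndarray:
        """Total UMI count of every spot."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def columns_for(self, barcodes) -> np.ndarray:
        """Positional column indices for a set of barcodes."""
        pos = self.spots.index.get_indexer(list(barcodes))
        if (pos < 0).any():
            missing = [b for b, p in zip(barcodes, pos) if p < 0]
            raise KeyError(f"barcodes not in dataset: {missing[:5]}")
        return pos

    def subset_counts(self, barcodes) -> sp.csr_matrix:
        return self.counts[:, self.columns_for(barcodes)]

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (spots x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.spots.copy(),
            var=pd.DataFrame(index=self.genes),
        )
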