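"""Depth normalization and sample-level quality control.

The normalization used throughout is the median-normalized average
(MNA): within a chosen spot cluster, every spot's counts are rescaled so
its total equals the cluster's median total (scale factor
``median(totals) / total``), and a gene's MNA is the mean of its
rescaled counts over the cluster. This equalizes sequencing depth
without leaving the count scale.

Two QC checks accompany it: housekeeping genes (e.g. Gapdh, Actb)
should track per-spot totals linearly, and the mean sequencing depth
should exceed ~50 000 UMI per spot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .core import SpotDataset
from .spatial import BinAssignment, ClusterSelection

__all__ = [
    "MnaMatrix",
    "LinearityReport",
    "QCReport",
    "mna_normalize",
    "binned_mna_profile",
    "housekeeping_linearity",
    "depth_qc",
]

#: Recommended minimum mean sequencing depth (UMI per spot).
DEPTH_THRESHOLD = 50_000.0

#: Default housekeeping-linearity pass threshold on R^2.
LINEARITY_R2_THRESHOLD = 0.5


@dataclass
class MnaMatrix:
    """Median-normalized counts for one spot cluster."""

    cluster: str
    genes: pd.Index
    barcodes: pd.Index
    normalized: np.ndarray  # genes x spots, dense float
    scale: np.ndarray  # per-spot factor median/total
    median_total: float

    @property
    def gene_mna(self) -> pd.Series:
        """Per-gene MNA: mean normalized count over the cluster."""
        return pd.Series(self.normalized.mean(axis=1), index=self.genes, name="mna")


@dataclass(frozen=True)
class LinearityReport:
    gene: str
    slope: float
    intercept: float
    r2: float
    passed: bool
    n_spots: int


@dataclass(frozen=True)
class QCReport:
    mean_umi_per_spot: float
    spot_totals: np.ndarray
    threshold: float
    passed: bool


def mna_normalize(ds: SpotDataset, cluster: ClusterSelection | list[str]) -> MnaMatrix:
    """Median-normalize the counts of a spot cluster.

    Every spot is scaled by ``median(cluster totals) / spot total`` so
    that all normalized spot totals equal the cluster median. Zero-total
    spots cannot be rescaled and are dropped with a warning.
    """
    if isinstance(cluster, ClusterSelection):
        name, barcodes = cluster.name, list(cluster.barcodes)
    else:
        name, barcodes = "cluster", list(cluster)
    if len(barcodes) == 0:
        raise ValueError("empty cluster")
    cols = ds.columns_for(barcodes)
    sub = ds.counts[:, cols]
    totals = np.asarray(sub.sum(axis=0), dtype=float).ravel()
    nz = totals > 0
    if not nz.any():
        raise ValueError(f"cluster {name!r} has no counts")
    if not nz.all():
        warnings.warn(
            f"cluster {name!r}: dropping {int((~nz).sum())} zero-total spot(s)",
            stacklevel=2,
        )
        sub = sub[:, nz]
        totals = totals[nz]
        barcodes = [b for b, keep in zip(barcodes, nz) if keep]
    median_total = float(np.median(totals))
    scale = median_total / totals
    normalized = sub.toarray().astype(float) * scale[np.newaxis, :]
    return MnaMatrix(
        cluster=name,
        genes=ds.genes,
        barcodes=pd.Index(barcodes),
        normalized=normalized,
        scale=scale,
        median_total=median_total,
    )


def binned_mna_profile(
    ds: SpotDataset,
    bins: BinAssignment,
    gene: str,
    max_bin: int = 9,
) -> pd.DataFrame:
    """Radial MNA profile of one gene in 100 µm annuli.

    Each annulus is normalized as its own cluster (the median is taken
    within the bin), and the gene's MNA is reported per bin out to
    ``max_bin`` (inclusive). Empty bins are missing (NaN).
    """
    if gene not in ds.genes:
        raise KeyError(f"gene {gene!r} not in dataset")
    eligible = (
        ds.spots["in_tissue"].to_numpy(bool) & ~ds.spots["artifact"].to_numpy(bool)
    )
    values = np.full(max_bin + 1, np.nan)
    ns = np.zeros(max_bin + 1, dtype=int)
    for k in range(max_bin + 1):
        in_bin = (bins.index == k) & eligible
        if not in_bin.any():
            continue
        barcodes = list(ds.spots.index[in_bin])
        try:
            mna = mna_normalize(ds, barcodes)
        except ValueError:
            continue  # all-zero bin stays missing
        values[k] = float(mna.gene_mna.loc[gene])
        ns[k] = len(mna.barcodes)
    w = bins.bin_width_um
    k = np.arange(max_bin + 1)
    return pd.DataFrame(
        {
            "bin_start_um": k * w,
            "bin_end_um": (k + 1) * w,
            "mna": values,
            "n": ns,
        }
    )


def housekeeping_linearity(
    ds: SpotDataset,
    gene: str,
    barcodes: list[str] | None = None,
    r2_threshold: float = LINEARITY_R2_THRESHOLD,
) -> LinearityReport:
    """Regress a housekeeping gene's raw counts on per-spot totals.

    Housekeeping transcripts should rise and fall with sequencing depth;
    a weak linear relationship flags a problematic sample. Requires at
    least 10 spots.
    """
    if gene not in ds.genes:
        raise KeyError(f"gene {gene!r} not in dataset")
    if barcodes is None:
        keep = (
            ds.spots["in_tissue"].to_numpy(bool)
            & ~ds.spots["artifact"].to_numpy(bool)
        )
        cols = np.flatnonzero(keep)
    else:
        cols = ds.columns_for(barcodes)
    if len(cols) < 10:
        raise ValueError("housekeeping linearity needs at least 10 spots")
    sub = ds.counts[:, cols]
    totals = np.asarray(sub.sum(axis=0), dtype=float).ravel()
    if np.ptp(totals) == 0:
        raise ValueError("zero variance in spot totals")
    gi = int(ds.genes.get_indexer([gene])[0])
    y = np.asarray(sub[gi, :].todense(), dtype=float).ravel()
    res = stats.linregress(totals, y)
    r2 = float(res.rvalue**2)
    return LinearityReport(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        passed=bool(r2 >= r2_threshold),
        n_spots=len(cols),
    )


def depth_qc(ds: SpotDataset, threshold: float = DEPTH_THRESHOLD) -> QCReport:
    """Check that mean UMI per spot meets the recommended depth."""
    totals = ds.spot_totals()
    mean = float(totals.mean()) if len(totals) else 0.0
    return QCReport(
        mean_umi_per_spot=mean,
        spot_totals=totals,
        threshold=float(threshold),
        passed=bool(mean >= threshold),
    )
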