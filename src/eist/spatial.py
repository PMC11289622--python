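"""Geometry around an implanted-electrode tract.

Distances from spot centroids to the tract, annular binning at a fixed
radial width (100 µm for expression and neuronal density, 10 µm for
staining intensity), selection of the electrode-site spot cluster and of
naïve-matched control sites, and radial profiles of neuron density and
fluorescence intensity.

Conventions
-----------
* All coordinates are planar and in micrometres.
* Annular bins are half-open: bin ``k`` covers ``[k*w, (k+1)*w)``.
* A tract is either a point (its centroid) or a simple polygon outline;
  with a polygon, distance is measured to the polygon (zero inside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "TractGeometry",
    "BinAssignment",
    "ClusterSelection",
    "IntensityField",
    "OUTSIDE",
    "spot_distances",
    "assign_bins",
    "select_cluster",
    "select_naive_sites",
    "neuronal_density_profile",
    "intensity_profile",
    "summarize_within",
]

#: Bin index used for spots beyond the maximum profiling radius.
OUTSIDE = -1


@dataclass(frozen=True)
class TractGeometry:
    """Location of the device tract in the tissue plane.

    Parameters
    ----------
    center_um : tuple of float
        Planar coordinate of the tract centroid (µm).
    polygon_um : ndarray of shape (n, 2), optional
        Vertices of a simple polygon outlining the tract. When present,
        distances are measured to the polygon (zero inside it).
    units : str
        Unit flag for the coordinate frame; must match the spot frame.
    """

    center_um: tuple[float, float]
    polygon_um: np.ndarray | None = None
    units: str = "um"

    def __post_init__(self) -> None:
        cx, cy = self.center_um
        if not (np.isfinite(cx) and np.isfinite(cy)):
            raise ValueError("tract center must be finite")
        if self.polygon_um is not None:
            poly = np.asarray(self.polygon_um, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError("polygon must be an (n>=3, 2) vertex array")
            object.__setattr__(self, "polygon_um", poly)
            shp = shapely.Polygon(poly)
            if not shp.is_valid:
                raise ValueError("tract polygon is self-intersecting")
            if not shp.covers(shapely.Point(cx, cy)):
                raise ValueError("tract polygon must contain its center")

    def as_shapely(self) -> shapely.Geometry:
        if self.polygon_um is not None:
            return shapely.Polygon(self.polygon_um)
        return shapely.Point(self.center_um)


@dataclass(frozen=True)
class BinAssignment:
    """Assignment of spots to concentric annuli around the tract."""

    bin_width_um: float
    index: np.ndarray  # int; OUTSIDE for d >= max_radius
    distances_um: np.ndarray
    max_radius_um: float

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.max_radius_um / self.bin_width_um))

    def members(self, k: int) -> np.ndarray:
        """Positional indices of the spots in bin ``k``."""
        return np.flatnonzero(self.index == k)


@dataclass(frozen=True)
class ClusterSelection:
    """A named set of spots, e.g. the electrode-site cluster."""

    name: str
    barcodes: tuple[str, ...]
    rmax_um: float
    center_um: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass(frozen=True)
class IntensityField:
    """A fluorescence-intensity image registered to the µm frame.

    ``values[i, j]`` is the pixel whose center is at
    ``(x_um[j], y_um[i])``.
    """

    values: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("intensity field must be 2-D")
        if v.shape != (len(self.y_um), len(self.x_um)):
            raise ValueError("field shape must match coordinate axes")
        object.__setattr__(self, "values", v)


def spot_distances(
    spots: pd.DataFrame, tract: TractGeometry, units: str = "um"
) -> np.ndarray:
    """Distance (µm) from each spot centroid to the tract.

    ``spots`` needs ``x_um``/``y_um`` columns. With a polygon tract the
    distance is the Euclidean distance to the polygon (0 inside); with a
    point tract it is the distance to the centroid.
    """
    if units != tract.units:
        raise ValueError(
            f"coordinate frame mismatch: spots in {units!r}, tract in {tract.units!r}"
        )
    xy = spots[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("spot coordinates must be finite")
    pts = shapely.points(xy)
    return shapely.distance(pts, tract.as_shapely())


def assign_bins(
    distances: np.ndarray, bin_width_um: float, max_radius_um: float
) -> BinAssignment:
    """Assign distances to half-open annular bins ``[k*w, (k+1)*w)``.

    Distances at or beyond ``max_radius_um`` get the ``OUTSIDE`` index.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    d = np.asarray(distances, dtype=float)
    idx = np.floor(d / bin_width_um).astype(int)
    idx[d >= max_radius_um] = OUTSIDE
    return BinAssignment(
        bin_width_um=float(bin_width_um),
        index=idx,
        distances_um=d,
        max_radius_um=float(max_radius_um),
    )


def _eligible(spots: pd.DataFrame) -> np.ndarray:
    in_tissue = spots.get("in_tissue")
    in_tissue = (
        np.ones(len(spots), bool) if in_tissue is None else in_tissue.to_numpy(bool)
    )
    artifact = spots.get("artifact")
    artifact = (
        np.zeros(len(spots), bool) if artifact is None else artifact.to_numpy(bool)
    )
    return in_tissue & ~artifact


def select_cluster(
    spots: pd.DataFrame,
    tract: TractGeometry,
    rmax_um: float = 300.0,
    name: str = "site",
) -> ClusterSelection:
    """Select in-tissue, non-artifact spots with centroid distance < rmax.

    The bound is strict, matching the half-open bins: a spot at exactly
    ``rmax_um`` belongs to the next annulus and is excluded.
    """
    d = spot_distances(spots, tract)
    keep = _eligible(spots) & (d < rmax_um)
    if not keep.any():
        raise ValueError(f"cluster {name!r}: no eligible spots within {rmax_um} um")
    return ClusterSelection(
        name=name,
        barcodes=tuple(spots.index[keep]),
        rmax_um=float(rmax_um),
        center_um=tuple(tract.center_um),
    )


def select_naive_sites(
    spots: pd.DataFrame,
    n_sites: int = 3,
    radius_um: float = 300.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 10_000,
) -> list[ClusterSelection]:
    """Draw non-overlapping random control sites in non-implanted tissue.

    Site centers are sampled uniformly from the spot-occupied area
    (jittered spot positions); candidates closer than ``2*radius_um`` to
    an accepted center are rejected. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    elig = _eligible(spots)
    xy = spots.loc[elig, ["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) == 0:
        raise ValueError("no eligible spots to place naive sites in")
    # jitter within half the nearest-neighbour scale so centers cover the area
    pitch = np.median(np.diff(np.unique(xy[:, 0]))) if len(xy) > 1 else radius_um
    centers: list[np.ndarray] = []
    sites: list[ClusterSelection] = []
    tries = 0
    while len(sites) < n_sites:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n_sites} disjoint sites of radius {radius_um} um "
                f"after {max_tries} tries; tissue extent too small"
            )
        tries += 1
        c = xy[rng.integers(len(xy))] + rng.uniform(-pitch / 2, pitch / 2, size=2)
        if any(np.hypot(*(c - c0)) <= 2 * radius_um for c0 in centers):
            continue
        tract = TractGeometry(center_um=(float(c[0]), float(c[1])))
        try:
            site = select_cluster(
                spots, tract, rmax_um=radius_um, name=f"naive_site_{len(sites)}"
            )
        except ValueError:
            continue
        centers.append(c)
        sites.append(site)
    return sites


def _annulus_areas_mm2(
    tract: TractGeometry, bin_width_um: float, n_bins: int
) -> np.ndarray:
    """Area (mm^2) of each annulus; polygon tracts use buffered outlines."""
    w = bin_width_um
    if tract.polygon_um is None:
        k = np.arange(n_bins)
        areas_um2 = np.pi * (((k + 1) * w) ** 2 - (k * w) ** 2)
    else:
        shp = tract.as_shapely()
        cum = np.array([shp.buffer((k + 1) * w).area for k in range(n_bins)])
        inner = np.concatenate([[shp.area], cum[:-1]])
        areas_um2 = cum - inner
    return areas_um2 / 1e6


def neuronal_density_profile(
    points: np.ndarray,
    tract: TractGeometry,
    bin_width_um: float = 100.0,
    max_radius_um: float = 1000.0,
) -> pd.DataFrame:
    """Neuron density (mm^-2) in annular bins around the tract.

    ``points`` is an (n, 2) array of neuron centroids (µm). Density per
    bin is the point count divided by the annulus area; with a polygon
    tract the annulus areas are measured from buffered outlines.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size and pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.size:
        d = shapely.distance(shapely.points(pts), tract.as_shapely())
    else:
        d = np.empty(0)
    ba = assign_bins(d, bin_width_um, max_radius_um)
    n_bins = ba.n_bins
    counts = np.bincount(ba.index[ba.index >= 0], minlength=n_bins)[:n_bins]
    areas = _annulus_areas_mm2(tract, bin_width_um, n_bins)
    if np.any(areas <= 0):
        raise ValueError("zero-area annulus bin")
    k = np.arange(n_bins)
    return pd.DataFrame(
        {
            "bin_start_um": k * bin_width_um,
            "bin_end_um": (k + 1) * bin_width_um,
            "n": counts,
            "area_mm2": areas,
            "density_per_mm2": counts / areas,
        }
    )


def intensity_profile(
    field: IntensityField,
    tract: TractGeometry,
    bin_width_um: float = 10.0,
    max_radius_um: float = 300.0,
) -> pd.DataFrame:
    """Mean pixel intensity in annular bins; empty bins are NaN."""
    xx, yy = np.meshgrid(field.x_um, field.y_um)
    xy = np.column_stack([xx.ravel(), yy.ravel()])
    d = shapely.distance(shapely.points(xy), tract.as_shapely())
    ba = assign_bins(d, bin_width_um, max_radius_um)
    vals = field.values.ravel()
    n_bins = ba.n_bins
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    inside = ba.index >= 0
    if inside.any():
        counts = np.bincount(ba.index[inside], minlength=n_bins)[:n_bins]
        sums = np.bincount(
            ba.index[inside], weights=vals[inside], minlength=n_bins
        )[:n_bins]
        nz = counts > 0
        means[nz] = sums[nz] / counts[nz]
    if np.any(counts == 0):
        warnings.warn("empty intensity bins recorded as missing", stacklevel=2)
    k = np.arange(n_bins)
    return pd.DataFrame(
        {
            "bin_start_um": k * bin_width_um,
            "bin_end_um": (k + 1) * bin_width_um,
            "n": counts,
            "mean_intensity": means,
        }
    )


def summarize_within(profile: pd.DataFrame, rmax_um: float = 300.0) -> float:
    """Collapse a radial profile to one scalar for the recordable radius.

    Density profiles pool counts over areas (total count / total area);
    intensity profiles return the pixel-weighted mean. The profile must
    cover ``[0, rmax_um)`` contiguously.
    """
    sub = profile[profile["bin_end_um"] <= rmax_um + 1e-9]
    if len(sub) == 0 or sub["bin_start_um"].iloc[0] > 1e-9:
        raise ValueError(f"profile does not cover [0, {rmax_um}) um")
    starts = sub["bin_start_um"].to_numpy()
    ends = sub["bin_end_um"].to_numpy()
    if not np.allclose(starts[1:], ends[:-1]) or ends[-1] < rmax_um - 1e-9:
        raise ValueError(f"profile does not cover [0, {rmax_um}) um contiguously")
    if "density_per_mm2" in sub.columns:
        return float(sub["n"].sum() / sub["area_mm2"].sum())
    if "mean_intensity" in sub.columns:
        ok = sub["n"] > 0
        if not ok.any():
            raise ValueError("no populated bins within rmax")
        w = sub.loc[ok, "n"].to_numpy(dtype=float)
        return float(np.average(sub.loc[ok, "mean_intensity"], weights=w))
    raise ValueError("unrecognized profile table")
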