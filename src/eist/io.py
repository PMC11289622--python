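"""Reading and writing the standard on-disk formats.

Spot datasets use the 10x convention: ``matrix.mtx`` (MatrixMarket
coordinate, genes x spots), ``features.tsv``, ``barcodes.tsv`` and a
``tissue_positions.csv`` with micrometre coordinates, plus a
``tract.json`` sidecar holding the tract geometry and artifact-spot
mask. Recordings are HDF5 with a ``signal`` dataset (channels x
samples, µV) and an ``fs_hz`` attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import SpotDataset
from .ephys import EphysRecording
from .spatial import TractGeometry

__all__ = [
    "save_spot_dataset",
    "load_spot_dataset",
    "save_recording",
    "load_recording",
]

_SPOT_FILES = ("matrix.mtx", "features.tsv", "barcodes.tsv",
               "tissue_positions.csv", "tract.json")


def save_spot_dataset(ds: SpotDataset, outdir: str | Path) -> Path:
    """Write a spot dataset in 10x convention plus a tract sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = sp.coo_matrix(ds.counts).astype(np.int64)
    scipy.io.mmwrite(outdir / "matrix.mtx", counts)
    pd.DataFrame(
        {"id": ds.genes, "name": ds.genes, "type": "Gene Expression"}
    ).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(ds.spots.index).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pos = ds.spots.reset_index()
    pos = pos.rename(columns={pos.columns[0]: "barcode"})
    cols = ["barcode", "in_tissue"]
    for c in ("row", "col"):
        if c in pos.columns:
            cols.append(c)
    cols += ["x_um", "y_um"]
    pos[cols].to_csv(outdir / "tissue_positions.csv", index=False)
    sidecar = {
        "center_um": list(ds.tract.center_um),
        "polygon_um": (
            ds.tract.polygon_um.tolist() if ds.tract.polygon_um is not None else None
        ),
        "artifact_barcodes": list(ds.spots.index[ds.spots["artifact"]]),
    }
    (outdir / "tract.json").write_text(json.dumps(sidecar, indent=1))
    return outdir


def load_spot_dataset(indir: str | Path) -> SpotDataset:
    """Read a spot dataset written by :func:`save_spot_dataset`.

    Raises named errors for missing files, barcode mismatches between
    the barcode list and the positions table, and non-integer counts.
    """
    indir = Path(indir)
    for fname in _SPOT_FILES:
        if not (indir / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {indir}")
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    if counts.dtype.kind == "f":
        if np.any(counts.data != np.round(counts.data)):
            raise ValueError("matrix.mtx contains non-integer counts")
        counts = counts.astype(np.int64)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    if counts.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    pos = pd.read_csv(indir / "tissue_positions.csv")
    extra = set(barcodes) ^ set(pos["barcode"])
    if extra:
        raise ValueError(f"barcode mismatch with positions table: {sorted(extra)[:5]}")
    pos = pos.set_index("barcode").loc[barcodes]
    sidecar = json.loads((indir / "tract.json").read_text())
    tract = TractGeometry(
        center_um=tuple(sidecar["center_um"]),
        polygon_um=(
            np.asarray(sidecar["polygon_um"], dtype=float)
            if sidecar.get("polygon_um")
            else None
        ),
    )
    pos["in_tissue"] = pos["in_tissue"].astype(bool)
    pos["artifact"] = pos.index.isin(sidecar.get("artifact_barcodes", []))
    return SpotDataset(
        counts=counts,
        genes=pd.Index(features[0]),
        spots=pos,
        tract=tract,
    )


def save_recording(rec: EphysRecording, path: str | Path) -> Path:
    """Write a recording as HDF5 (dataset ``signal``, attribute ``fs_hz``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("signal", data=rec.signal)
        dset.attrs["units"] = "uV"
        f.attrs["fs_hz"] = rec.fs_hz
    return path


def load_recording(path: str | Path) -> EphysRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing recording file {path}")
    with h5py.File(path, "r") as f:
        if "signal" not in f:
            raise ValueError(f"{path} has no 'signal' dataset")
        signal = f["signal"][...]
        fs = float(f.attrs.get("fs_hz", f["signal"].attrs.get("fs_hz", 0.0)))
    if fs <= 0:
        raise ValueError(f"{path} missing fs_hz attribute")
    return EphysRecording(signal=signal, fs_hz=fs)
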