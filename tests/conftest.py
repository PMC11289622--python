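import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from eist.core import SpotDataset
from eist.spatial import TractGeometry


def nb_dataset(
    n_genes: int,
    n_spots: int,
    mean: float = 50.0,
    phi: float = 0.0,
    seed: int = 0,
) -> SpotDataset:
    """A flat (no spatial effect) NB count dataset on a line of spots."""
    rng = np.random.default_rng(seed)
    if phi == 0:
        counts = rng.poisson(mean, (n_genes, n_spots))
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mean), (n_genes, n_spots))
    spots = pd.DataFrame(
        {
            "x_um": np.arange(n_spots) * 100.0,
            "y_um": 0.0,
            "in_tissue": True,
            "artifact": False,
        },
        index=pd.Index([f"s{i}" for i in range(n_spots)], name="barcode"),
    )
    return SpotDataset(
        counts=sp.csr_matrix(counts),
        genes=pd.Index([f"g{i}" for i in range(n_genes)]),
        spots=spots,
        tract=TractGeometry(center_um=(0.0, 0.0)),
    )


@pytest.fixture
def grid_spots() -> pd.DataFrame:
    """A 21x21 spot lattice at 100 um pitch centred on (1000, 1000)."""
    rows, cols = np.mgrid[0:21, 0:21]
    return pd.DataFrame(
        {
            "x_um": cols.ravel() * 100.0,
            "y_um": rows.ravel() * 100.0,
            "in_tissue": True,
            "artifact": False,
        },
        index=pd.Index(
            [f"s{r:02d}_{c:02d}" for r, c in zip(rows.ravel(), cols.ravel())],
            name="barcode",
        ),
    )
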