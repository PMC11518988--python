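import numpy as np
import pandas as pd
import pytest

from marrowmap import CellMap


def make_cellmap(coords, phenotypes, area_mm2=1.0, sample_id="S1",
                 group="AML", markers=None):
    """Build a CellMap from raw coordinate/phenotype lists."""
    coords = np.asarray(coords, dtype=float)
    cells = pd.DataFrame({
        "cell_id": [f"{sample_id}_c{i}" for i in range(len(coords))],
        "x_um": coords[:, 0] if len(coords) else [],
        "y_um": coords[:, 1] if len(coords) else [],
        "phenotype": list(phenotypes),
    })
    for name, flags in (markers or {}).items():
        cells[f"marker_{name}"] = np.asarray(flags, dtype=bool)
    return CellMap(sample_id=sample_id, group=group, cells=cells,
                   tissue_area_mm2=area_mm2)


@pytest.fixture
def cellmap_factory():
    return make_cellmap


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
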