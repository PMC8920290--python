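import numpy as np
import pandas as pd
import pytest

from mifspat import CellTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cell_table(coords, flags: dict, sample_id="S1", subject_id="P1", compartment="unknown"):
    """Build a CellTable directly from coordinate and marker-flag arrays."""
    coords = np.asarray(coords, dtype=float)
    cells = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]})
    for marker, vals in flags.items():
        cells[marker] = np.asarray(vals, dtype=np.int8)
    cells["compartment"] = compartment
    return CellTable(sample_id=sample_id, subject_id=subject_id, cells=cells, markers=tuple(flags))


@pytest.fixture
def t_cell_table():
    """Ten cells with CD3/CD8/FOXP3 flags, three of them conflicting."""
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 100, size=(10, 2))
    cd3 = [1, 1, 1, 1, 1, 0, 0, 0, 1, 1]
    cd8 = [1, 1, 1, 0, 0, 0, 1, 0, 0, 1]
    fox = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    return make_cell_table(coords, {"CD3": cd3, "CD8": cd8, "FOXP3": fox})
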