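import numpy as np
import pandas as pd
import pytest

from tamspatial import DEFAULT_PANEL, SampleTable, default_catalogue


def make_sample(cell_specs, sample_id="S1", tumor_area=1.0, stroma_area=1.0,
                clinical=None):
    """Build a SampleTable from compact per-cell dicts.

    Each spec: {"pos": ["CD68", "CD163"], "x": 0, "y": 0,
    "compartment": "tumor"}; unspecified markers are negative.
    """
    rows = []
    for i, spec in enumerate(cell_specs):
        positives = {m for m in spec.get("pos", ())}
        row = {
            "cell_id": spec.get("cell_id", f"c{i}"),
            "core_id": "core1",
            "x_um": float(spec.get("x", i * 10.0)),
            "y_um": float(spec.get("y", 0.0)),
            "compartment": spec.get("compartment", "tumor"),
        }
        for m in DEFAULT_PANEL:
            row[f"{m}_pos"] = m in positives
        if "intensity" in spec:
            for m, v in spec["intensity"].items():
                row[f"{m}_int"] = float(v)
        rows.append(row)
    return SampleTable(sample_id=sample_id, cells=pd.DataFrame(rows),
                       tumor_area_mm2=tumor_area, stroma_area_mm2=stroma_area,
                       clinical=clinical or {})


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
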