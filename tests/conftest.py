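import numpy as np
import pandas as pd
import pytest

from hexiht import CellMap, CompartmentGeometry


def make_cellmap(
    xy: np.ndarray,
    compartment: str | np.ndarray = "tumor",
    case_id: str = "t1",
    geometry: CompartmentGeometry | None = None,
    **marker_flags,
) -> CellMap:
    """Assemble a CellMap from coordinate and flag arrays."""
    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1]})
    df["compartment"] = compartment
    for name, flags in marker_flags.items():
        df[name] = flags
    return CellMap(case_id=case_id, cells=df,
                   geometry=geometry or CompartmentGeometry())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_cellmap(rng):
    """A 3×3 mm tumor map with ~2000 cells/mm² and 30% PR positivity."""
    n = rng.poisson(2000 * 9)
    xy = rng.uniform(0, 3000, size=(n, 2))
    pr = (rng.random(n) < 0.3).astype(float)
    return make_cellmap(xy, pr=pr)
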