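import numpy as np
import pandas as pd
import pytest

from cnkit.tissue import CellTable


def make_table(xy, cts, image="img0", sample="d0", group="g0", start=0):
    """Small helper to build a CellTable from coordinates and CTs."""
    xy = np.asarray(xy, float)
    n = len(xy)
    img = [image] * n if isinstance(image, str) else list(image)
    smp = [sample] * n if isinstance(sample, str) else list(sample)
    df = pd.DataFrame(
        {
            "group": [group] * n,
            "sample": smp,
            "image": img,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cell_type": list(cts),
        },
        index=pd.Index([f"c{start + i}" for i in range(n)], name="cell_id"),
    )
    return CellTable(df)


@pytest.fixture
def square_table():
    """Four cells at unit-square corners, two CTs."""
    return make_table(
        [(0, 0), (1, 0), (0, 1), (1, 1)], ["a", "a", "b", "b"]
    )


@pytest.fixture
def two_block_table():
    """Two well-separated blocks of cells with disjoint CT vocabularies."""
    rng = np.random.default_rng(7)
    left = rng.uniform(0, 10, size=(40, 2))
    right = rng.uniform(0, 10, size=(40, 2)) + np.array([100.0, 0.0])
    xy = np.vstack([left, right])
    cts = ["a"] * 40 + ["b"] * 40
    return make_table(xy, cts)


@pytest.fixture
def planted_tissue():
    """Moderate planted-CN tissue shared by identification tests."""
    from cnkit.synthetic import SyntheticTissueSpec, simulate_tissue

    return simulate_tissue(
        SyntheticTissueSpec(n_cells=1200, n_cns=3, noise=0.05, seed=11)
    )
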