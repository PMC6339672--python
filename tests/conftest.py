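import numpy as np
import pytest

import irtlink as il
from irtlink.calibrate import CalibOptions, concurrent_calibrate
from irtlink.core import ItemBank, ItemParams


@pytest.fixture(scope="session")
def binary_item():
    return ItemParams("bin", 1.0, (0.0,))


@pytest.fixture(scope="session")
def three_cat_item():
    return ItemParams("tri", 1.0, (-1.0, 1.0))


@pytest.fixture(scope="session")
def small_bank():
    """Two 3-item instruments with varied categories and slopes."""
    items = [
        ItemParams("A_i0", 0.8, (-1.0, 0.2), {"A"}),
        ItemParams("A_i1", 1.2, (-0.5, 0.5, 1.3), {"A"}),
        ItemParams("A_i2", 1.0, (0.3,), {"A"}),
        ItemParams("B_i0", 1.4, (-1.4, -0.2, 0.9), {"B"}),
        ItemParams("B_i1", 0.9, (0.0, 0.8), {"B"}),
        ItemParams("B_i2", 1.1, (-0.6,), {"B"}),
    ]
    return ItemBank(items)


@pytest.fixture(scope="session")
def linked_sim():
    """A small 2-dataset linked study used across calibration tests."""
    spec = il.SimSpec(
        n_datasets=2,
        n_instruments=2,
        items_per_instrument=6,
        n_cat_range=(3, 4),
        instruments_per_dataset=(2, 2),
        n_per_dataset=500,
        seed=314,
    )
    design = il.generate_link_design(spec)
    bank = il.generate_bank(spec)
    dists = il.GroupDist(
        {"D0": 0.0, "D1": 0.25}, {"D0": 1.0, "D1": 1.1}, "D0"
    )
    data = il.simulate_responses(bank, design, dists, spec)
    return {"spec": spec, "design": design, "bank": bank, "dists": dists, "data": data}


@pytest.fixture(scope="session")
def linked_fit(linked_sim):
    fit = concurrent_calibrate(
        linked_sim["data"],
        linked_sim["design"],
        "GPCM",
        CalibOptions(tol=1e-4, max_iter=300, compute_se=False),
    )
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(20250905)
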