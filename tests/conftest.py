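import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from trammelnet import (
    CatchItem,
    Fate,
    NettingWallRecord,
    PriceTable,
    WallType,
)


@pytest.fixture
def toy_walls():
    """Two nets of two walls each, one boat/trip per net."""
    rows = []
    for j, (boat, wtype) in enumerate([("B1", WallType.PMF), ("B2", WallType.MMF)]):
        for k in (1, 2):
            rows.append(NettingWallRecord(
                wall_id=f"N{j}W{k}", trip_id=f"T{j}", boat_id=boat,
                net_id=f"N{j}", wall_index=k, wall_type=wtype,
                depth_m=90.0, soak_h=45.0))
    return rows


@pytest.fixture
def toy_items():
    return [
        CatchItem("i1", "N0W1", "Scorpaena scrofa", Fate.MARKETABLE,
                  length_cm=30.0, weight_kg=0.5,
                  commercial_category="Scorpaena scrofa"),
        CatchItem("i2", "N0W2", "Raja clavata", Fate.DISCARD,
                  length_class_upper_cm=60.0, weight_kg=1.2,
                  alive_on_arrival=False),
        CatchItem("i3", "N1W1", "Palinurus elephas", Fate.DISCARD,
                  length_cm=7.5, weight_kg=0.2, alive_on_arrival=True),
    ]


@pytest.fixture
def toy_prices():
    return PriceTable([
        ("Scorpaena scrofa", "T0", 17.68),
        ("Palinurus elephas", "T0", 58.0),
        ("Palinurus elephas", "T1", 62.0),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
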