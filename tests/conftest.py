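import numpy as np
import pytest

from bioticlimit.spatial import EnvStack, GridSpec, OccurrenceRecord, OccurrenceSet, RasterGrid


@pytest.fixture
def small_spec() -> GridSpec:
    return GridSpec(lon_min=-76.0, lon_max=-75.0, lat_min=3.0, lat_max=4.0, cell_size=0.1)


@pytest.fixture
def small_stack(small_spec) -> EnvStack:
    rng = np.random.default_rng(0)
    layers = [
        RasterGrid(small_spec, rng.standard_normal(small_spec.shape), name=f"v{i}")
        for i in range(3)
    ]
    return EnvStack(layers)


def make_points(coords, protocol="specimen", species="test") -> OccurrenceSet:
    return OccurrenceSet(
        [OccurrenceRecord(lon=lo, lat=la, protocol=protocol) for lo, la in coords], species
    )
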