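import numpy as np
import pytest

import habscape as h


@pytest.fixture(scope="session")
def small_spec():
    return h.SyntheticSpec(shape=(60, 60), seed=11, restricted_fraction=0.05)


@pytest.fixture(scope="session")
def landscape(small_spec):
    """Shared synthetic calibration bundle: drivers, t0, t1, subtype, mask."""
    return h.generate_landscape_pair(small_spec)


@pytest.fixture(scope="session")
def fitted(landscape):
    drivers, lu0, lu1, _, _ = landscape
    return h.LandUseModel(lu0, lu1, drivers, interval_years=8.0).fit(
        seed=3, epochs=80
    )


@pytest.fixture()
def two_class_table():
    return [(1, "a"), (2, "b")]
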