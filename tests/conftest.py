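import numpy as np
import pytest

from smlm.locio import ROI, make_table


@pytest.fixture
def window():
    """The standard 3 x 3 µm analysis ROI."""
    return ROI(0.0, 0.0, 3000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Ten localizations over three frames, two channels."""
    return make_table(
        frame=[1, 1, 1, 2, 2, 2, 3, 3, 3, 3],
        x=[100.0, 900.0, 1500.0, 200.0, 1000.0, 2900.0, 50.0, 60.0, 2000.0, 2500.0],
        y=[100.0, 800.0, 1500.0, 300.0, 1100.0, 2800.0, 55.0, 65.0, 2100.0, 2600.0],
        uncertainty=[8.0, 12.0, 15.0, 9.0, 25.0, 11.0, 7.0, 30.0, 10.0, 14.0],
        intensity=[500, 800, 300, 900, 700, 400, 600, 200, 1000, 350],
        channel=[1, 1, 1, 1, 2, 2, 1, 1, 2, 2],
    )
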