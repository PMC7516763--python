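import numpy as np
import pytest

import picselect as ps


@pytest.fixture(scope="session")
def hald_data():
    """(y, X) arrays of the bundled Hald cement benchmark."""
    frame = ps.hald()
    return frame["Y"].to_numpy(), frame[["X1", "X2", "X3", "X4"]].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(20200306)
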