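import numpy as np
import pandas as pd
import pytest

import allompower as ap


@pytest.fixture(scope="session")
def alligator_spec():
    return ap.alligator_like_spec()


@pytest.fixture(scope="session")
def alligator_table(alligator_spec):
    """Synthetic 108-specimen table under the published study conditions."""
    return ap.simulate_dataset(alligator_spec, 108, seed=1234)


@pytest.fixture()
def tiny_table():
    """Noise-free 3-variable table with slopes 0.5, 1.0 and 2.0."""
    L = np.array([10.0, 25.0, 60.0, 150.0, 400.0, 650.0])
    frame = pd.DataFrame(
        {
            "ref": L,
            "half": L**0.5,
            "iso": L.copy(),
            "double": L**2,
        },
        index=[f"S{i}" for i in range(L.size)],
    )
    return ap.MeasurementTable(frame, "ref")
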