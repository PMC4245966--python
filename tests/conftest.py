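import numpy as np
import pandas as pd
import pytest

import svaseq as sv


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated dataset at the generator defaults (m=1000, n=12)."""
    return sv.simulate_dataset(sv.SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def four_sample_design():
    """Binary two-group design, no adjustment variables."""
    return sv.DesignInfo(
        sample_ids=["s1", "s2", "s3", "s4"],
        primary=pd.DataFrame({"group": ["ctl", "ctl", "trt", "trt"]}),
        known_adjust=pd.DataFrame(index=range(4)),
    )
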