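import numpy as np
import pytest

import fesemg as f


@pytest.fixture(scope="session")
def short_recording():
    """10 s worst-case contaminated recording (shared across read-only tests)."""
    return f.make_recording(duration_s=10.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
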