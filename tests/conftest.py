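import numpy as np
import pytest

from bbbkit.data_model import DescriptorTable
from bbbkit.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synthetic():
    """Small but well-separated two-class table with a ground-truth manifest."""
    spec = SyntheticSpec(
        n_active=150, n_inactive=50, n_informative=5, n_noise=5,
        n_correlated_pairs=1, n_structural_keys=2, separation=4.0, seed=7,
    )
    return generate(spec)


@pytest.fixture
def descriptor_table(rng):
    """Plain 2-class, 4-descriptor table without missing values."""
    import pandas as pd

    n = 60
    frame = pd.DataFrame(
        {
            "alpha": rng.normal(size=n),
            "beta": rng.normal(size=n),
            "gamma": rng.normal(size=n),
            "delta": rng.normal(size=n),
        },
        index=[f"c{i}" for i in range(n)],
    )
    labels = np.array([1] * 40 + [0] * 20)
    return DescriptorTable(frame=frame, set_tag="2D"), labels
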