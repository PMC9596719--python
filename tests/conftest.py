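import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_cluster_values():
    """16 points in 3 well-separated clusters; the adaptive search picks
    k = 3 here (p-value falls from k=2 to k=3 and rises at k=4)."""
    r = np.random.default_rng(4)
    return np.concatenate(
        [r.normal(0, 0.5, 5), r.normal(5, 0.5, 5), r.normal(10, 0.5, 6)]
    )
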