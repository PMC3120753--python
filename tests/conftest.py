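import numpy as np
import pandas as pd
import pytest

from salivaclock import default_config, simulate_dataset
from salivaclock.io import BetaMatrix


def make_beta(values, probe_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down default simulation shared across read-only tests."""
    cfg = default_config(seed=11, n_probes=600, module_sizes=(80, 60),
                        n_age_probes=20)
    return simulate_dataset(cfg)
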