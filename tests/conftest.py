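import numpy as np
import pandas as pd
import pytest

from fractiomics.config import SimulationConfig
from fractiomics.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-window bundle with ground truth, shared across tests."""
    cfg = SimulationConfig(n_windows=12, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def mid_bundle():
    """A 30-window bundle (~3,000 genes) for recovery tests."""
    cfg = SimulationConfig(n_windows=30, seed=13)
    return simulate_dataset(cfg)


def draw_truncated_ks(rng, n=2000, mus=(0.34, 0.96), sds=(0.15, 0.42), weights=(0.5, 0.5)):
    """Draws from the planted two-peak Ks mixture, truncated at zero."""
    mus, sds = np.asarray(mus), np.asarray(sds)
    comp = rng.choice(len(mus), size=n, p=np.asarray(weights))
    x = rng.normal(mus[comp], sds[comp])
    bad = x < 0
    while bad.any():
        x[bad] = rng.normal(mus[comp[bad]], sds[comp[bad]])
        bad = x < 0
    return x


def make_tpm(rows: dict[str, list[float]], columns: list[str]) -> pd.DataFrame:
    """Small TPM matrix helper: {gene: values} with condition_rep columns."""
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns, dtype=float)
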