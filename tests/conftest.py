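import numpy as np
import pandas as pd
import pytest

from gaclock import BetaMatrix, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(n_samples=60, n_probes=300, n_causal=20, seed=11)
    return simulate_dataset(cfg)


def random_beta_matrix(rng, n_probes=50, n_samples=10, missing_frac=0.0):
    vals = rng.uniform(0.001, 0.999, size=(n_probes, n_samples))
    if missing_frac:
        holes = rng.random(vals.shape) < missing_frac
        vals[holes] = np.nan
    probes = pd.Index([f"cg{i:05d}" for i in range(n_probes)], name="probe_id")
    samples = [f"s{j:03d}" for j in range(n_samples)]
    return BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples))
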