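import dataclasses

import numpy as np
import pytest

from rwdry.kinetics import moisture_ratio
from rwdry.synthetic import SyntheticConfig, generate_experiment


@pytest.fixture(scope="session")
def noiseless_cfg() -> SyntheticConfig:
    """Single-replicate, noise-free study conditions (exact Page curves)."""
    return SyntheticConfig(noise_sd_mr=0.0, replicates=1)


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_cfg):
    return generate_experiment(noiseless_cfg)


@pytest.fixture(scope="session")
def page_surface(noiseless_bundle):
    """(temperature, time) -> MR dataset pooled over all noiseless runs."""
    X = np.vstack([
        np.column_stack([np.full(r.time_min.size, r.temperature_C), r.time_min])
        for r in noiseless_bundle.drying_runs
    ])
    y = np.concatenate([moisture_ratio(r).mr for r in noiseless_bundle.drying_runs])
    return X, y


@pytest.fixture(scope="session")
def n1_cfg(noiseless_cfg) -> SyntheticConfig:
    """Noise-free conditions with Page exponent 1 (pure exponential decay)."""
    return dataclasses.replace(noiseless_cfg, page_n=1.0)
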