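import numpy as np
import pandas as pd
import pytest

import rtmconform as rc


def make_slope_data(n_participants=3, n_items=10, mean_slope=-0.4,
                    slope_sd=0.15, noise_sd=0.3, seed=42):
    """Centered items with genuine between-participant slope spread, for
    exercising the random-slope model away from its boundary."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_participants):
        slope = mean_slope + slope_sd * rng.standard_normal()
        r = rng.standard_normal(n_items)
        r -= r.mean()
        c = slope * r + noise_sd * rng.standard_normal(n_items)
        rows.append(pd.DataFrame({"participant_id": f"p{k}", "r": r, "c": c}))
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def toy_items():
    return make_slope_data()


@pytest.fixture(scope="session")
def small_config():
    # 6 per group x 30 items keeps pipeline-level tests fast
    return rc.GeneratorConfig(n_per_group=6, n_items=30, seed=11)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return rc.generate_experiment(small_config)


@pytest.fixture(scope="session")
def default_trials():
    return rc.generate_experiment(rc.GeneratorConfig(seed=5))


@pytest.fixture(scope="session")
def default_items(default_trials):
    return rc.preprocess(default_trials)
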