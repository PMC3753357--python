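import dataclasses

import pytest

from lakechla import ForestHyperparams, LakeChlaModel
from lakechla.synthetic import SyntheticConfig, generate_lakes


@pytest.fixture(scope="session")
def dataset48():
    """Default 48-lake synthetic dataset (both strata present)."""
    cfg = dataclasses.replace(SyntheticConfig(), rng_seed=11)
    records, observations, truth = generate_lakes(cfg)
    return cfg, records, observations, truth


@pytest.fixture(scope="session")
def fitted48(dataset48):
    """Both forests fitted on the 48-lake dataset (moderate tree count)."""
    _, records, observations, _ = dataset48
    model = LakeChlaModel(records, observations, hyperparams=ForestHyperparams(n_trees=300))
    return model.fit(seed=5)


@pytest.fixture(scope="session")
def coarse_grid(fitted48):
    """0.1-step scenario grid shared across scenario tests."""
    import numpy as np

    axis = tuple(np.round(np.arange(0.0, 2.0001, 0.1), 10))
    return fitted48.scenario_grid(m_s_axis=axis, m_li_axis=axis)
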