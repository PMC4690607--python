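import numpy as np
import pytest

import vsdwave.synthdata as sd
from vsdwave import forest, simulate_feature_table


@pytest.fixture(scope="session")
def default_table():
    """Feature table from the committed default configuration and seed."""
    table, truth = simulate_feature_table()
    return table, truth


@pytest.fixture(scope="session")
def default_split(default_table):
    table, _ = default_table
    cfg = sd.default_config()
    return forest.stratified_split(table, forest.SplitSpec(seed=cfg.seed))


@pytest.fixture(scope="session")
def trained_default(default_split):
    train, valid = default_split
    cfg = sd.default_config()
    model = forest.train_forest(train, n_trees=50, seed=cfg.seed)
    return model, train, valid


def clean_single_membrane_config(**overrides):
    """Recording config with one membrane and no noise, motion or bleach."""
    conds = tuple(
        sd.ConditionConfig(
            label=c.label,
            beat_rate_mean=60.0,
            beat_rate_sd=0.0,
            pulse_mean=c.pulse_mean,
            pulse_sd={k: 0.0 for k in c.pulse_sd},
            cell_level_fraction=0.0,
        )
        for c in sd.DEFAULT_CONDITIONS
    )
    kwargs = dict(
        conditions=conds,
        n_lines=10000,
        line_period=0.002,
        n_membranes=1,
        motion_amplitude=0.0,
        bleach_b=0.0,
        bleach_d=0.0,
        noise_sd=0.0,
    )
    kwargs.update(overrides)
    return sd.SynthConfig(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
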