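import numpy as np
import pytest

from reachkin import (
    NoiseConfig,
    PipelineConfig,
    TrialCondition,
    make_subject,
    process_trial,
    simulate_trial,
)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def clean_subject(cfg):
    """Noise-free left-side subject with random sensor mountings."""
    return make_subject(11, side="left", noise=NoiseConfig.zero(seed=11), config=cfg)


@pytest.fixture(scope="session")
def noisy_subject(cfg):
    """Default-noise left-side subject."""
    return make_subject(13, side="left", config=cfg)


@pytest.fixture(scope="session")
def clean_trial(clean_subject, cfg):
    """One noise-free rendered trial (truth, sensor set)."""
    cond = TrialCondition("AF", "BH", "Top3")
    return simulate_trial(clean_subject, cond, trial_seed=42, config=cfg)


@pytest.fixture(scope="session")
def clean_processed(clean_subject, clean_trial, cfg):
    truth, sset = clean_trial
    return truth, process_trial(sset, clean_subject.calibration, cfg, clean_subject.biases, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
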