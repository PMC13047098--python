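import numpy as np
import pytest

from aonrvi.config import SimConfig, TrialSpec
from aonrvi.synthetic_field import generate_trial


@pytest.fixture(scope="session")
def mini_config() -> SimConfig:
    """A small two-trial design (one with a duplicated low rate) that keeps
    scenes and point streams tiny while exercising the full structure."""
    trials = (
        TrialSpec(
            trial_id="A",
            fnr=200.0,
            treatments=(
                ("20%FNR", 40.0),
                ("40%FNR", 80.0),
                ("70%FNR", 140.0),
                ("100%FNR", 200.0),
                ("130%FNR", 260.0),
            ),
            residue_fraction=0.2,
            subplot_length_m=18.0,
            plot_width_m=6.0,
        ),
        TrialSpec(
            trial_id="B",
            fnr=180.0,
            treatments=(
                ("50%FNR-a", 90.0),
                ("50%FNR-b", 90.0),
                ("70%FNR", 126.0),
                ("100%FNR", 180.0),
                ("130%FNR", 234.0),
            ),
            residue_fraction=0.45,
            subplot_length_m=18.0,
            plot_width_m=6.0,
        ),
    )
    cfg = SimConfig(
        trials=trials,
        transects_per_trial=3,
        points_per_subplot=8,
        artifact_fraction=0.05,
        seed=42,
    )
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def mini_trial(mini_config):
    """Design + truth for the first mini trial."""
    return generate_trial(mini_config, 0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
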