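import numpy as np
import pytest

from camopt.colour import enumerate_dichromat_gamut
from camopt.model import train_ensemble
from camopt.nnet import TrainingConfig
from camopt.observer import ObserverGroundTruth, SimulationConfig, generate_dataset

FAST_TRAINING = TrainingConfig(max_epochs=80, patience=10)


@pytest.fixture(scope="session")
def dichromat_gamut():
    """Full enumeration of the simulated protanope gamut (default
    transfer/rounding conventions); shared because it takes seconds."""
    return enumerate_dichromat_gamut()


@pytest.fixture(scope="session")
def tiny_gt():
    return ObserverGroundTruth(sigma=0.2, n_participants=3)


@pytest.fixture(scope="session")
def tiny_trials(tiny_gt):
    """One condition, 3 participants x 200 trials: enough signal to fit."""
    cfg = SimulationConfig(
        environments=("forest",),
        chromacies=("trichromat",),
        n_participants=3,
        n_trials=200,
    )
    return generate_dataset(cfg, tiny_gt, seed=42)


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_trials):
    """3-member bootstrap ensemble at desk scale, shared across tests."""
    return train_ensemble(
        tiny_trials,
        n_boot=3,
        base_seed=7,
        n_blocks=2,
        n_participants=3,
        condition=("forest", "trichromat"),
        config=FAST_TRAINING,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
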