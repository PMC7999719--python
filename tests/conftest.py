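import numpy as np
import pytest

from abnremap import EventTrain, Experiment, GeneratorConfig
from abnremap.synthetic import generate_experiment, generate_null_experiment


def make_train(times, amplitudes=None, neuron="n1", mouse="m1", session="preC"):
    times = np.asarray(times, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones_like(times)
    return EventTrain(
        neuron_id=neuron,
        mouse_id=mouse,
        session=session,
        times=times,
        amplitudes=np.asarray(amplitudes, dtype=float),
    )


@pytest.fixture
def train_factory():
    return make_train


@pytest.fixture(scope="session")
def crossfade_experiment():
    """Default planted-effect experiment shared across tests."""
    return generate_experiment(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def null_experiment():
    """Fully null experiment: every detection is a false positive."""
    return generate_null_experiment(GeneratorConfig(seed=23))


def build_experiment(trains, durations=None, hypnogram=None):
    kwargs = {"session_durations": durations} if durations else {}
    return Experiment(
        trains={(t.mouse_id, t.neuron_id, t.session): t for t in trains},
        hypnogram=hypnogram,
        **kwargs,
    )


@pytest.fixture
def experiment_factory():
    return build_experiment
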