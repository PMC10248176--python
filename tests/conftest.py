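import numpy as np
import pytest

from gazeintent import evaluation, networks, preprocess, simulate, training

SMALL_SIM = simulate.SimulationConfig(n_movements=60, warmup_movements=2)
PROFILE = simulate.ParticipantProfile()


@pytest.fixture(scope="session")
def small_logs():
    """Two small sessions (60 movements each) shared across test modules."""
    return [simulate.simulate_session(SMALL_SIM, PROFILE, seed=s) for s in (7, 8)]


@pytest.fixture(scope="session")
def datasets(small_logs):
    return preprocess.prepare_datasets(small_logs)


@pytest.fixture(scope="session")
def trained_encoder(datasets):
    """A small encoder trained briefly on the shared data: not accurate, but a
    real trained model for evaluation-layer behavior tests."""
    net = networks.build_network(
        "encoder", networks.EncoderConfig(C=8, H=2, ff=8, N_x=1), seed=3)
    tcfg = training.TrainConfig(max_epochs=5, patience=5, seed=3)
    training.train_network(net, datasets.train, datasets.val, tcfg)
    return net


@pytest.fixture(scope="session")
def stream_eval(trained_encoder, datasets):
    """A stored per-timestep gated evaluation record on the test stream."""
    return evaluation.continuous_stream_eval(
        trained_encoder, datasets.test_stream, th_l=0.3, n_passes=10, n_p=10,
        rng=np.random.default_rng(11))
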