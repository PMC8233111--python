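import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def symmetric_network(rng, n, zero_edges=0):
    """Random symmetric zero-diagonal weight matrix in [0, 1]."""
    W = rng.uniform(0, 1, (n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    iu = np.triu_indices(n, 1)
    if zero_edges:
        drop = rng.choice(len(iu[0]), size=zero_edges, replace=False)
        W[iu[0][drop], iu[1][drop]] = 0.0
        W[iu[1][drop], iu[0][drop]] = 0.0
    return W


@pytest.fixture(scope="session")
def small_subject():
    """One small simulated subject shared by pipeline-level tests.

    Four channels, 1 hour, 10-min bouts, sleep coupling twice wake, no
    circadian modulation; re-referencing disabled (the simulator has no
    shared reference and common-average mixing dominates at 4 channels).
    """
    from circanet import simdata, preprocess, connectivity

    cfg = simdata.SimulationConfig(
        n_channels=4, fs=200, duration=3600, seed=7,
        bout_mean_wake=600, bout_mean_sleep=600,
        circadian_amplitude=0.0, artifact_rate=2.0)
    schedule = simdata.generate_schedule(cfg)
    recording, truth = simdata.generate_recording(cfg, schedule)
    epochs = preprocess.preprocess(recording, rereference=False)
    nulls = connectivity.build_all_nulls(epochs, n_iter=200, seed=7)
    tensor = connectivity.epoch_networks(epochs, nulls)
    return {"config": cfg, "schedule": schedule, "recording": recording,
            "truth": truth, "epochs": epochs, "nulls": nulls, "tensor": tensor}
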