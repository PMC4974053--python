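import numpy as np
import pytest

from caltask import synthetic


@pytest.fixture(scope="session")
def session_table():
    cfg = synthetic.SessionConfig(n_trials=120, seed=11,
                                  hit_rate=0.9, fa_rate=0.2)
    return synthetic.generate_session(cfg)


@pytest.fixture(scope="session")
def small_traces(session_table):
    """40-neuron uniform-mixture tensor with moderate noise."""
    mix = {a: 1 / 6 for a in synthetic.ARCHETYPES}
    return synthetic.generate_traces(session_table, mix, n_neurons=40,
                                     noise_sd=0.1, seed=12)


@pytest.fixture(scope="session")
def benchmark_traces():
    """600-neuron low-noise archetype benchmark (100 per class on average)."""
    cfg = synthetic.SessionConfig(n_trials=180, seed=21,
                                  hit_rate=0.95, fa_rate=0.1)
    table = synthetic.generate_session(cfg)
    mix = {a: 1 / 6 for a in synthetic.ARCHETYPES}
    traces, truth = synthetic.generate_traces(table, mix, n_neurons=600,
                                              noise_sd=0.05, seed=22)
    return traces, truth


@pytest.fixture(scope="session")
def soma_movie():
    """Noiseless 20-soma movie with step-transient traces."""
    rng = np.random.default_rng(7)
    T = 100
    traces = np.zeros((20, T))
    for i in range(20):
        on = rng.integers(5, 80)
        traces[i, on:on + 10] = 1.0
    mcfg = synthetic.MovieConfig(frame_size=(160, 160), n_cells=20,
                                 noise_sd=0.0, seed=8)
    movie, truth = synthetic.generate_movie(mcfg, traces)
    return movie, truth, traces
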