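import numpy as np
import pytest

import circawave as cw


@pytest.fixture(scope="session")
def noiseless_movie():
    """48x48 bilateral movie, 3 h phase gradient, no noise — shared truth."""
    params = cw.MovieParams(
        height=48, width=48, frame_interval=0.5, n_cycles=5, period=24.0,
        phase_gradient_span=3.0, noise_model="none", seed=11,
    )
    movie, truth = cw.make_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def uniform_movie():
    """Disc movie with zero phase gradient: every pixel oscillates in phase."""
    params = cw.MovieParams(
        height=40, width=40, frame_interval=0.5, n_cycles=5, period=24.0,
        phase_gradient_span=0.0, mask_shape="disc", noise_model="none", seed=5,
    )
    movie, truth = cw.make_movie(params)
    return params, movie, truth


def cosine_series(period=24.0, dt=0.5, duration=120.0, amplitude=1.0, phase_h=0.0):
    t = np.arange(0.0, duration + dt / 2, dt)
    return cw.TimeSeries(0.0, dt, amplitude * np.cos(2 * np.pi * (t - phase_h) / period))
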