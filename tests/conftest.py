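import numpy as np
import pytest

from flickermap import Movie
from flickermap.synthetic import (
    FlickerMovieParams,
    generate_flicker_movie,
    random_flicker_events,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_movie():
    """Pure-noise movie: stationary baseline + Gaussian camera noise."""
    rng = np.random.default_rng(7)
    black, f0, sigma = 100.0, 500.0, 20.0
    data = black + f0 + rng.normal(0, sigma, size=(600, 24, 24))
    return Movie(data=data, frame_interval=1 / 9.54, pixel_size=0.1, black_level=black)


@pytest.fixture(scope="session")
def default_flicker_suite():
    """The default synthetic flicker benchmark: 20 implanted events, z in [8, 15]."""
    params = FlickerMovieParams()
    events = random_flicker_events(params, n_events=20, peak_z=(8.0, 15.0), seed=42)
    movie, truth = generate_flicker_movie(params, events, seed=42)
    return movie, truth
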