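import dataclasses

import numpy as np
import pytest

import ucnpscore as u


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240119)


@pytest.fixture(scope="session")
def small_config():
    """Fast scoring configuration for small phantoms in unit tests."""
    return u.ScoringConfig(window_size=65, gaussian_sigma=12.0, stride=8)


@pytest.fixture(scope="session")
def small_spec():
    """Small, quickly scorable phantom field."""
    return u.PhantomSpec(shape=(256, 256), cell_count=40, seed=11)


def ring_patch(n: int, radius: float, thickness: float, amplitude: float) -> np.ndarray:
    """Isolated ring on zero background, centered on the patch."""
    c = (n - 1) / 2.0
    d = np.arange(n) - c
    dist = np.hypot(d[:, None], d[None, :])
    patch = np.zeros((n, n))
    patch[np.abs(dist - radius) <= thickness / 2] = amplitude
    return patch


@pytest.fixture(scope="session")
def cpa_small(small_spec, small_config):
    """Small four-level CPA series scored through the default-band pipeline."""
    series = u.generate_cpa_series(small_spec, n_per_level=3, seed=5)
    scores = {
        lvl: [u.area_score(u.score_image(out.ucnp, small_config)) for out in outs]
        for lvl, outs in series.items()
    }
    return series, scores
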