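import numpy as np
import pytest
from hypothesis import settings

import seedspec as ss
from seedspec.hypercube import WavelengthAxis
from seedspec.segment import SpectraTable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    return WavelengthAxis(np.linspace(1000.0, 1800.0, 5))


@pytest.fixture
def tiny_scene():
    """A small, fast plate: 2x2 grid of seeds, clean class signal."""
    return ss.SceneSpec(
        n_rows=2, n_cols=2, seed_radius_px=3, image_shape=(30, 30),
        wavelengths_nm=np.linspace(1000.0, 1800.0, 40),
        delta_magnitude=0.05, scatter_sd=0.01, baseline_drift_sd=0.005,
        noise_sd=0.005, rng_seed=7)


@pytest.fixture
def labelled_table(rng):
    """SpectraTable with 8 seeds (4 per class), 5 px each, separable signal."""
    n_seeds, px, bands = 8, 5, 12
    X, y, sid = [], [], []
    for s in range(n_seeds):
        cls = s % 2
        base = np.linspace(0.4, 0.6, bands)
        for _ in range(px):
            spec = base + 0.1 * cls + rng.normal(0, 0.01, bands)
            X.append(spec)
            y.append(cls)
            sid.append(s + 1)
    return SpectraTable(np.array(X), np.array(y), np.array(sid),
                        WavelengthAxis(np.linspace(1000, 1800, bands)))
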