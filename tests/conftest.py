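import numpy as np
import pytest

from wormlapse import PixelGrid, WormConfig, fit_body_axis, generate_cohort, generate_movie


@pytest.fixture(scope="session")
def grid():
    return PixelGrid(1.0)


@pytest.fixture(scope="session")
def straight_axis():
    """90 um straight axis along +x, ventral side -y."""
    pts = np.column_stack([np.linspace(0.0, 90.0, 10), np.zeros(10)])
    return fit_body_axis(pts, (45.0, -20.0))


@pytest.fixture(scope="session")
def sine_axis():
    """Gently bent axis: sine midline, amplitude 40 um, wavelength 200 um."""
    x = np.linspace(0.0, 200.0, 10)
    pts = np.column_stack([x, 40.0 * np.sin(2 * np.pi * x / 200.0)])
    return fit_body_axis(pts, (100.0, -60.0))


@pytest.fixture(scope="session")
def movie():
    """One fully rendered synthetic animal (fixed seed)."""
    return generate_movie(WormConfig(seed=1))


@pytest.fixture(scope="session")
def cohort():
    """Twenty synthetic animals, tables only, default (measured) jitter."""
    return generate_cohort(WormConfig(seed=7), n_animals=20, render=False)


@pytest.fixture(scope="session")
def wide_jitter_cohort():
    """Twenty animals with 0.8 h stage-duration jitter for timing statistics."""
    cfg = WormConfig(seed=11, stage_sd_h=(0.8, 0.8, 0.8, 0.8))
    return generate_cohort(cfg, n_animals=20, render=False)
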