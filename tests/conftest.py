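import numpy as np
import pandas as pd
import pytest

from peptidome.io import Spectrum
from peptidome.synthetic import SimulationConfig


@pytest.fixture
def grid():
    return 1000.0 + 0.5 * np.arange(8001)  # m/z 1000-5000, 0.5 Da


@pytest.fixture
def small_config():
    """Desk-scale cohort used across module tests."""
    return SimulationConfig(
        n_cases=10,
        n_controls=10,
        n_replicates_per_subject=2,
        mz_range=(1000.0, 5000.0),
        n_common_peaks=40,
        noise_sd=0.3,
        calibration_error_ppm=100.0,
        seed=11,
    )


def gaussian_spectrum(grid, centers_areas, fwhm_of=lambda mz: mz / 800.0,
                      noise_sd=0.0, baseline=None, seed=0, **meta):
    """Hand-built spectrum: Gaussians + optional baseline + noise."""
    rng = np.random.default_rng(seed)
    y = np.zeros_like(grid)
    for c, a in centers_areas:
        sigma = fwhm_of(c) / 2.3548200450309493
        y += a / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    if baseline is not None:
        y = y + baseline(grid)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, grid.size)
    return Spectrum(grid, np.clip(y, 0, None), **meta)


@pytest.fixture
def toy_metadata():
    n = 20
    return pd.DataFrame(
        {
            "group": ["ccRCC"] * 10 + ["control"] * 10,
            "age": np.linspace(40, 70, n),
            "sex": ["M", "F"] * 10,
        },
        index=pd.Index([f"S{i:02d}" for i in range(n)], name="subject_id"),
    )
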