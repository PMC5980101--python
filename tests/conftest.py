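import numpy as np
import pytest

from pheegmark import SyntheticConfig, generate_dataset
from pheegmark.features import FitWindow

# Small, fast study design shared across tests: full 3-strain x 8-day
# structure but few animals/channels and a coarse 5 s time grid (the
# default 2-51 min post-injection window still fits the 61 min record).
SMALL_KW = dict(
    n_animals_per_strain=3,
    n_channels=2,
    step_s=5.0,
    duration_s=3660.0,
)


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Noise-free dataset with a known planted slope in one band."""
    cfg = SyntheticConfig(
        **SMALL_KW, noise_sd=0.0, spike_rate=0.0, outlier_curve_rate=0.0, seed=11
    )
    cfg.dose_slope_effects[0, 2, 2] = 0.5  # strain SHR, day D2, band Delta
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    cfg = SyntheticConfig(
        **SMALL_KW, noise_sd=0.1, spike_rate=0.002, outlier_curve_rate=0.0, seed=7
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_window():
    return FitWindow(2.0, 49.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
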