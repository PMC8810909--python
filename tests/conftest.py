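"""Shared fixtures.

The two replicate studies (parameter recovery at survey scale and the
residual-autocovariate correction) are expensive, so they run once per
session and are shared by the acceptance-style tests and the property
checks that consume them.
"""

import numpy as np
import pytest

from urbancline.studies import rac_study, recovery_study


@pytest.fixture(scope="session")
def recovery_results():
    """50 simulate-and-refit replicates at survey scale (43 cities,
    ~27k observations, generative coefficients = reported values)."""
    return recovery_study(n_replicates=50, seed=1)


@pytest.fixture(scope="session")
def rac_results():
    """50 replicates of the spatial-noise + autocovariate-refit study."""
    return rac_study(n_replicates=50, seed=1)


@pytest.fixture(scope="session")
def small_frame():
    """A modest simulated frame for single-fit oracle checks."""
    from urbancline.simulate import SimConfig, simulate_frame

    cfg = SimConfig(
        n_cities=8,
        city_area_range=(5_000.0, 40_000.0),
        n_obs_per_city_range=(200, 320),
        obs_count_log_median=250.0,
        obs_count_log_sigma=0.3,
        target_total_obs=None,
        beta=np.array([-1.2, 0.4, -0.8, 0.2, 0.3, -0.1, 0.15, 0.1]),
        sigma_city=0.6,
        seed=42,
    )
    frame, _, _, _ = simulate_frame(cfg)
    return frame
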