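"""Shared configuration for the analysis drivers.

Every driver regenerates the same deterministic synthetic study, so the
scripts can be run independently and in any order.  Tables land under
``results/analysis``.
"""

from pathlib import Path

import numpy as np

from urbancline.simulate import SimConfig, simulate_study

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"

#: A mid-sized survey: large enough for stable coefficients, small
#: enough that each driver runs in seconds.
STUDY_CONFIG = SimConfig(
    n_cities=20,
    city_area_range=(8_000.0, 120_000.0),
    n_obs_per_city_range=(101, 1_200),
    obs_count_log_median=300.0,
    obs_count_log_sigma=0.8,
    target_total_obs=8_000,
    sigma_city=1.0,
    vote_error_rate=0.03,
    seed=20_260_920,
)


def get_study():
    return simulate_study(STUDY_CONFIG)


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS


def scratchdir() -> Path:
    """Row-level tables (one row per observation) go here, not results."""
    SCRATCH.mkdir(parents=True, exist_ok=True)
    return SCRATCH
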