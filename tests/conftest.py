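"""Shared fixtures: compact synthetic deployments for fast unit tests.

The mini dive-type specs are deliberately small (3-minute dives) so a
whole deployment fits in a few seconds of CPU; full-scale study conditions
are exercised in the acceptance tests.
"""

import numpy as np
import pytest

from deepdive import synthetic_data as sd
from deepdive.kinematics import compute_jerk, estimate_orientation
from deepdive.dive_segmentation import detect_dives, dive_metrics, segment_phases

MINI_SPECS = (
    sd.DiveTypeSpec("short_shallow", 80.0, 10.0, 5.0, 0.4, 0.9, 0.1, 1.0, 0.1,
                    p_foraging=0.0),
    sd.DiveTypeSpec("mid_depth", 300.0, 25.0, 12.0, 0.8, 1.0, 0.1, 1.2, 0.1,
                    p_foraging=1.0, gyration_rate=1.2),
)
MINI_MIXTURE = (0.5, 0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_deployment():
    """Noise-free 4-dive deployment at 16 Hz with generating angles kept."""
    series, truth = sd.simulate_deployment(
        MINI_SPECS, MINI_MIXTURE, 4, fs=16.0, seed=7,
        deployment_id="clean00", location="TestSite",
        lead_in_s=90.0, surface_median_s=120.0,
        noise=0.0, jerk_transients=False, keep_angles=True,
    )
    return series, truth


@pytest.fixture(scope="session")
def noisy_deployment():
    """Default-noise 5-dive deployment at 16 Hz."""
    series, truth = sd.simulate_deployment(
        MINI_SPECS, MINI_MIXTURE, 5, fs=16.0, seed=21,
        deployment_id="noisy00", location="TestSite",
        lead_in_s=90.0, surface_median_s=120.0,
    )
    return series, truth


@pytest.fixture(scope="session")
def analysed_clean(clean_deployment):
    """Orientation, jerk, segmented dives and metrics for the clean record."""
    series, truth = clean_deployment
    orientation = estimate_orientation(series, smooth_s=0.5)
    jerk = compute_jerk(series)
    dives = detect_dives(series, 40.0)
    metrics = []
    for d in dives:
        segment_phases(d, orientation)
        metrics.append(dive_metrics(d, series, orientation, jerk))
    return {
        "series": series,
        "truth": truth,
        "orientation": orientation,
        "jerk": jerk,
        "dives": dives,
        "metrics": metrics,
    }
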