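import numpy as np
import pytest

from multidrive.driving import DrivingParams
from multidrive.search import SearchParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_driving_params():
    """Noise- and drift-free dynamics with the point-car lane convention:
    the setting of the analytic micro-oracles."""
    return DrivingParams(
        speed_kmh=60.0, sigma_d=0.0, curvature_drift_mps=0.0, car_width_m=0.0
    )


@pytest.fixture
def emma_params():
    """Oculomotor constants used by the hand-evaluated timing examples."""
    return SearchParams(
        n_items=6,
        item_frequency=0.01,
        encoding_constant_s=0.006,
        eccentricity_constant=0.4,
        t_prep_s=0.135,
        t_exec_s=0.070,
        t_sacc_s_per_deg=0.002,
    )
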