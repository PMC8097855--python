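import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methyloutlier import BetaMatrix, Calibration, SampleGroups

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> BetaMatrix:
    """4 markers × 6 samples; m1/m2 discriminate, m3 noisy, m4 has a hole."""
    values = pd.DataFrame(
        {
            "s1": [0.60, 0.70, 0.30, 0.10],
            "s2": [0.55, 0.65, 0.05, np.nan],
            "s3": [0.80, 0.90, 0.50, 0.20],
            "s4": [0.05, 0.02, 0.40, 0.10],
            "s5": [0.10, 0.05, 0.01, 0.30],
            "s6": [0.02, 0.08, 0.60, 0.05],
        },
        index=["m1", "m2", "m3", "m4"],
    )
    return BetaMatrix(values)


@pytest.fixture
def small_groups() -> SampleGroups:
    return SampleGroups(
        {
            "s1": ("case", "lymphoma"),
            "s2": ("case", "lymphoma"),
            "s3": ("case", "lymphoma"),
            "s4": ("control", "glioma"),
            "s5": ("control", "glioma"),
            "s6": ("control", "glioma"),
        }
    )


@pytest.fixture
def calibration() -> Calibration:
    return Calibration(
        reference_ct_actb=25.0,
        reference_copies=606.0,
        control_delta_ct={"cg054": 1.0, "SCG3": 2.0},
    )
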