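import numpy as np
import pytest

from psmarad.synthetic import CohortConfig, fixture_phantom
from psmarad.volumes import LesionMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort configuration for pipeline-level tests."""
    return CohortConfig(
        n_patients=8,
        lesions_per_patient=(2, 3),
        grid_shape=(28, 28, 18),  # 70 x 70 x 72 mm frame
        pet_visibility_rate=0.95,
        mri_visibility_rate=0.85,
        false_positive_rate=0.05,
        seed=11,
    )


@pytest.fixture
def ball_mask():
    """Digital ball of radius 5 mm on a 1 mm grid."""
    return _ball(5.0)


def _ball(radius_mm: float, spacing: float = 1.0) -> LesionMask:
    n = int(2 * radius_mm / spacing) + 5
    c = (n // 2) * spacing
    idx = np.indices((n, n, n)) * spacing
    d2 = sum((idx[a] - c) ** 2 for a in range(3))
    return LesionMask((d2 <= radius_mm**2).astype(np.uint8), (spacing,) * 3, lesion_id=f"ball{radius_mm}")


@pytest.fixture
def make_ball():
    return _ball


@pytest.fixture(params=["constant_5", "checkerboard_4", "two_level_bar", "two_blob_5", "ramp_4"])
def phantom(request):
    return fixture_phantom(request.param)
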