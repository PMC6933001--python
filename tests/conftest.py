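import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctvlsm.synthetic import SimulationConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def tiny_config(**overrides) -> SimulationConfig:
    """Desk-scale config for fast unit tests (24^3 grid, small cohort)."""
    base = dict(
        grid_shape=(24, 24, 24),
        brain_radii_mm=(9.0, 10.0, 9.0),
        ventricle_radii_mm=(2.5, 4.0, 2.5),
        ventricle_centers_mm=((-3.5, 0.0, 1.5), (3.5, 0.0, 1.5)),
        lesion_radius_range_mm=(4.0, 6.0),
        critical_center_mm=(-3.0, -2.0, 1.0),
        critical_radii_mm=(3.0, 3.0, 3.0),
        n_controls=8,
        n_patients=12,
        seed=42,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return generate_cohort(tiny_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
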