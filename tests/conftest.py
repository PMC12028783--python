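import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from alleloscreen.synthetic import DesignConfig, TreatmentEffect


@pytest.fixture
def small_design():
    return DesignConfig(
        treatments=["CK", "A", "B"], control="CK", seeds_per_dish=30,
        dishes_per_treatment=4, rng_seed=7,
    )


@pytest.fixture
def neutral_effect():
    return TreatmentEffect(
        p_germ_day7=0.8, p_germ_day3_given_day7=0.7,
        mean_radicle_mm=12.0, mean_germ_mm=8.0, mean_height_cm=2.8,
        cv_morpho=0.25, physio_cv=0.1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
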