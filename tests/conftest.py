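import numpy as np
import pytest

from ebusplan import InjectionPlan, ModelParameters, synthetic_tumor


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Patient-calibrated parameter set (fitted k_sum, literature k_i)."""
    return ModelParameters.patient_fitted()


@pytest.fixture()
def single_site_plan() -> InjectionPlan:
    return InjectionPlan(np.array([[0.0, 0.0, 0.0]]), np.array([8.0]))


@pytest.fixture()
def five_site_plan() -> InjectionPlan:
    from ebusplan import default_five_site_plan

    return default_five_site_plan()


@pytest.fixture(scope="session")
def small_sphere():
    """4 cm^3 sphere at 0.15 cm spacing — fast fixture for planning tests."""
    return synthetic_tumor("sphere", volume=4.0, spacing=0.15)
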