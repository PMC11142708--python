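import numpy as np
import pytest

from kinbind import (EnvironmentGeometry, ExperimentCondition,
                     ParameterVector, PhysicalParams)


@pytest.fixture(scope="session")
def phys():
    return PhysicalParams()


@pytest.fixture(scope="session")
def geom():
    return EnvironmentGeometry(trap_center=np.array([0.0, 0.0, 400.0]))


@pytest.fixture(scope="session")
def adp_params():
    return ParameterVector.fitted_adp()


@pytest.fixture(scope="session")
def diffusion_params():
    return ParameterVector.fitted_diffusion()


@pytest.fixture(scope="session")
def fast_condition():
    """A condition where binding is quick (sub-second means)."""
    return ExperimentCondition(motor_length=45.0, gap=0.0)


@pytest.fixture(scope="session")
def fast_summary(adp_params):
    """Small summary dataset over quick conditions, for inference tests."""
    from kinbind.synthetic import generate_dataset
    design = [ExperimentCondition(motor_length=L, gap=g)
              for L in (33.0, 45.0) for g in (0.0, 20.0)]
    ds = generate_dataset(adp_params, design=design, n_per_condition=40,
                          seed=17)
    return ds.summary
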