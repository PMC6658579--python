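import numpy as np
import pytest

from fitloop.estimator import EstimatorComponent, make_component
from fitloop.world import Bump, WorldConfig


@pytest.fixture
def scalar_double() -> EstimatorComponent:
    """The scalar map u -> 2u with identity nonlinearity."""
    return EstimatorComponent(
        id="double",
        m=1,
        n=1,
        kind="linear_monotone",
        A=np.array([[2.0]]),
        b=np.zeros(1),
        nonlinearity="identity",
    )


@pytest.fixture
def identity_component() -> EstimatorComponent:
    return EstimatorComponent(
        id="identity",
        m=2,
        n=2,
        kind="linear_monotone",
        A=np.eye(2),
        b=np.zeros(2),
        nonlinearity="identity",
    )


@pytest.fixture
def square_component() -> EstimatorComponent:
    """A random well-conditioned 4x4 monotone-nonlinear component."""
    return make_component(
        {"id": "sq", "m": 4, "n": 4, "cond_cap": 1e3, "ensemble": "gaussian"}, seed=7
    )


@pytest.fixture
def one_bump_world() -> WorldConfig:
    return WorldConfig(
        dim_form=2,
        landscape=(Bump(center=(0.0, 0.0), height=1.0, width=1.0),),
        init_scale=0.0,
        dt=0.01,
    )


@pytest.fixture
def two_bump_world() -> WorldConfig:
    return WorldConfig(
        dim_form=2,
        landscape=(
            Bump(center=(2.0, 2.0), height=1.0, width=1.0),
            Bump(center=(-2.0, -2.0), height=0.6, width=1.0),
        ),
        init_scale=1.0,
        dt=0.01,
    )
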