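import math

import pytest

from dcmodel import (
    ModelParameters,
    anchored_truth_fixture,
    default_parameters,
    integrate,
    propagate,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def anchor():
    """Canonical t=5 anchor state plus the reference (C, N) pairs."""
    return anchored_truth_fixture()


@pytest.fixture(scope="session")
def end_error():
    """Absolute C error at t=20 of a scheme run from the t=5 anchor."""
    params = default_parameters()
    state0 = anchored_truth_fixture().state
    truth = propagate(state0, 15.0, params)

    def _run(method: str, dt: float) -> float:
        n = round(15.0 / dt)
        assert math.isclose(n * dt, 15.0), "dt must divide the 15-year window"
        traj = integrate(method, state0, params, dt, state0.t + n * dt)
        return abs(traj.states[-1].C - truth.C)

    return _run
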