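import numpy as np
import pytest

from nmdose.fixtures import (
    FixtureSpec,
    make_conserving_phantom,
    make_toy_nuclide,
    make_weighted_phantom,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=12345)


@pytest.fixture(scope="session")
def conserving_phantom(spec):
    return make_conserving_phantom(spec)


@pytest.fixture(scope="session")
def mixed_nuclide(spec):
    return make_toy_nuclide(spec, "mixed")


@pytest.fixture()
def weighted_pair(spec):
    """Male/female weighted phantoms sharing masses and SAF draws."""
    from nmdose.phantom import Sex

    male = make_weighted_phantom(spec, sex=Sex.MALE)
    female = make_weighted_phantom(spec, sex=Sex.FEMALE)
    return male, female


def ode_chain_oracle(lambdas, branches, a0, times, rtol=1e-12):
    """Stiff-ODE reference solution for a serial decay chain (activities)."""
    from scipy.integrate import solve_ivp

    lambdas = np.asarray(lambdas, float)
    branches = np.asarray(branches, float)
    n = lambdas.size

    def rhs(t, y):
        dy = -lambdas * y
        dy[1:] += branches * lambdas[:-1] * y[:-1]
        return dy

    n0 = np.zeros(n)
    n0[0] = a0 / lambdas[0]
    times = np.asarray(times, float)
    sol = solve_ivp(
        rhs, (0.0, float(times.max())), n0, t_eval=times, method="Radau",
        rtol=rtol, atol=1e-18,
    )
    assert sol.success
    return lambdas[:, None] * sol.y
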