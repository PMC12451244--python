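import numpy as np
import pytest

from nutkin.model import GrowthLawParams, simulate


@pytest.fixture(scope="session")
def params_default():
    return GrowthLawParams()


@pytest.fixture(scope="session")
def traj_default(params_default):
    """Five nutation periods at package defaults (shared across tests)."""
    return simulate(params_default)


@pytest.fixture(scope="session")
def traj_no_growth():
    """Pure oscillation: no mean growth, differential growth only."""
    p = GrowthLawParams(Edot_max=0.0)
    return simulate(p)


@pytest.fixture(scope="session")
def traj_straight():
    """Pure elongation: no differential growth, stays straight."""
    p = GrowthLawParams(dE_max=0.0)
    return simulate(p)


def rigid_rotating_rod(theta0=0.2, T=2.5, length=100.0, n_markers=51, n_times=501, n_periods=2):
    """Analytic trajectory of a rigid straight rod with θ(t) = θ0·sin(2πt/T).

    No growth, no curvature: isolates the projection geometry.
    """
    from nutkin.model import RachisTrajectory

    times = np.linspace(0.0, n_periods * T, n_times)
    s0 = np.linspace(0.0, length, n_markers)
    theta_t = theta0 * np.sin(2 * np.pi * times / T)
    s = np.tile(s0, (n_times, 1))
    C = np.zeros_like(s)
    theta = np.repeat(theta_t[:, None], n_markers, axis=1)
    xy = np.stack(
        [s * np.cos(theta_t)[:, None], s * np.sin(theta_t)[:, None]], axis=-1
    )
    return RachisTrajectory(
        times=times, material_ids=s0, s=s, C=C, theta=theta, xy=xy,
        apex_s=np.full(n_times, length), params=None,
    )
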