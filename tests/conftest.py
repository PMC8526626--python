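import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from slithersim import BodyGrid, EnvironmentParams, GaitParams, SimConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    """Default arclength grid (201 trapezoid nodes)."""
    return BodyGrid(201)


@pytest.fixture(scope="session")
def default_gait():
    return GaitParams()  # eps=7, k=1, no lifting


@pytest.fixture(scope="session")
def anisotropic_env():
    return EnvironmentParams(mu_t_ratio=2.0)


@pytest.fixture(scope="session")
def fast_sim():
    """Reduced-cost numerical protocol for property tests."""
    return SimConfig(n_s=101, rtol=1e-6, atol=1e-8)


def make_synthetic_trajectory(com_fn, vel_fn, alpha_fn, alpha_t_fn=None, n_periods=5.0,
                              samples_per_period=100, gait=None, env=None):
    """Build a Trajectory from closed-form COM/orientation histories."""
    from slithersim.dynamics import Trajectory

    sim = SimConfig(n_periods=n_periods, samples_per_period=samples_per_period)
    t = np.linspace(0.0, n_periods, int(n_periods * samples_per_period) + 1)
    com = np.array([com_fn(ti) for ti in t], dtype=float)
    vel = np.array([vel_fn(ti) for ti in t], dtype=float)
    alpha = np.array([alpha_fn(ti) for ti in t], dtype=float)
    alpha_t = (
        np.array([alpha_t_fn(ti) for ti in t], dtype=float)
        if alpha_t_fn
        else np.zeros_like(t)
    )
    states = np.column_stack([com, vel, alpha, alpha_t])
    return Trajectory(
        times=t,
        states=states,
        gait=gait or GaitParams(),
        env=env or EnvironmentParams(),
        sim=sim,
    )
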