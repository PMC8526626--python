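"""Equations of motion for the centre of mass and mean orientation.

With the body shape prescribed by the curvature wave, the only dynamical
degrees of freedom are the centre of mass ``x_bar`` and the mean orientation
``alpha_bar``.  Balancing friction against inertia (internal forces and
torques integrate to zero) gives the reduced equations

    Fr * x_bar_tt = int_0^1 F ds
    Fr * alpha_bar_tt = (1/J) int_0^1 (x - x_bar) x F ds
                        + (Fr/J) int_0^1 ( I[n] . I[t alpha_t^2]
                                           - I[t] . I[t I[kappa_tt]] ) ds

where ``alpha_t = alpha_bar_t + I[kappa_t]``, ``J = int (x - x_bar)^2 ds`` is
the moment of inertia, and the second line is the inertial correction from the
prescribed shape change.  The 6-dimensional state
``(x_bar, x_bar_t, alpha_bar, alpha_bar_t)`` is integrated with an adaptive
Runge-Kutta scheme; the velocity-regularised Coulomb force is continuous in
time so no event handling is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .kinematics import (
    BodyConfiguration,
    BodyGrid,
    GaitParams,
    curvature_time_derivatives,
    lifting_modulation,
    mean_zero_integral,
    reconstruct_configuration,
)
from .friction import EnvironmentParams, friction_force_density, normalized_weight
from . import _kernels

__all__ = [
    "SnakeState",
    "SimConfig",
    "Trajectory",
    "moment_of_inertia",
    "net_force_torque",
    "period_averaged_loads",
    "acceleration",
    "simulate",
]


@dataclass
class SnakeState:
    """Reduced dynamical state (COM, mean orientation, and their rates)."""

    com: np.ndarray = field(default_factory=lambda: np.zeros(2))
    com_vel: np.ndarray = field(default_factory=lambda: np.zeros(2))
    alpha_bar: float = 0.0
    alpha_bar_t: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        self.com_vel = np.asarray(self.com_vel, dtype=float)

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.com[0], self.com[1], self.com_vel[0], self.com_vel[1], self.alpha_bar, self.alpha_bar_t]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray, t: float) -> "SnakeState":
        return cls(com=y[0:2], com_vel=y[2:4], alpha_bar=float(y[4]), alpha_bar_t=float(y[5]), time=t)


@dataclass(frozen=True)
class SimConfig:
    """Numerical protocol: duration, grid, integrator tolerances, sampling."""

    n_periods: float = 10.0
    n_s: int = 201
    rtol: float = 1e-8
    atol: float = 1e-10
    samples_per_period: int = 100
    averaging_window: float = 1.0  # trailing window length, periods

    def __post_init__(self) -> None:
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.samples_per_period < 100:
            raise ValueError("output sampling must be >= 100 samples/period")
        if not 0 < self.averaging_window <= self.n_periods:
            raise ValueError("averaging window must lie within the simulated span")

    def make_grid(self) -> BodyGrid:
        return BodyGrid(n_s=self.n_s)


@dataclass
class Trajectory:
    """Uniformly sampled time series of the reduced state plus run metadata."""

    times: np.ndarray
    states: np.ndarray  # (n_samples, 6)
    gait: GaitParams
    env: EnvironmentParams
    sim: SimConfig

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must increase strictly")

    @property
    def com(self) -> np.ndarray:
        return self.states[:, 0:2]

    @property
    def com_vel(self) -> np.ndarray:
        return self.states[:, 2:4]

    @property
    def alpha_bar(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def alpha_bar_t(self) -> np.ndarray:
        return self.states[:, 5]

    def state_at(self, i: int) -> SnakeState:
        return SnakeState.from_vector(self.states[i], float(self.times[i]))

    def window_slice(self, window: tuple[float, float]) -> np.ndarray:
        t0, t1 = window
        if t1 - t0 < 1.0 - 1e-9:
            raise ValueError("window must cover at least one full period")
        mask = (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)
        if mask.sum() < 2:
            raise ValueError("window does not overlap sampled times")
        return np.nonzero(mask)[0]

    def default_window(self) -> tuple[float, float]:
        t_end = float(self.times[-1])
        return (t_end - self.sim.averaging_window, t_end)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "x": self.com[:, 0],
                "y": self.com[:, 1],
                "alpha_bar": self.alpha_bar,
                "vx": self.com_vel[:, 0],
                "vy": self.com_vel[:, 1],
                "alpha_bar_t": self.alpha_bar_t,
            }
        )

    def metadata(self) -> dict:
        from . import __version__

        env = asdict(self.env)
        fmap = env.pop("friction_map", None)
        return {
            "slithersim_version": __version__,
            "gait": asdict(self.gait),
            "env": env,
            "friction_map": _map_metadata(self.env.friction_map),
            "sim": asdict(self.sim),
        }


def _map_metadata(fmap) -> list | None:
    if fmap is None:
        return None
    out = []
    for p in fmap.primitives:
        d = asdict(p)
        d["type"] = type(p).__name__.lower()
        if "values" in d:
            d["values"] = np.asarray(d["values"]).tolist()
        out.append(d)
    return out


def moment_of_inertia(config: BodyConfiguration, grid: BodyGrid | None = None) -> float:
    """Nondimensional moment of inertia ``J = int (x - x_bar)^2 ds``."""
    grid = grid or config.grid
    rel = config.centered()
    return float(grid.integrate(np.einsum("ij,ij->i", rel, rel)))


def _cross_z(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def net_force_torque(
    config: BodyConfiguration,
    weight: np.ndarray,
    env: EnvironmentParams,
) -> tuple[np.ndarray, float]:
    """Instantaneous net friction force (2-vector) and torque about the COM."""
    grid = config.grid
    force = friction_force_density(config, weight, env)
    f_net = grid.quad_weights @ force
    torque = float(grid.integrate(_cross_z(config.centered(), force)))
    return f_net, torque


def period_averaged_loads(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Net force and torque averaged over a window of steady-state motion."""
    window = window or traj.default_window()
    idx = traj.window_slice(window)
    grid = traj.sim.make_grid()
    forces = np.empty((idx.size, 2))
    torques = np.empty(idx.size)
    for j, i in enumerate(idx):
        state = traj.state_at(i)
        config = reconstruct_configuration(state, traj.gait, grid)
        n_hat = lifting_modulation(grid.s_values, state.time, traj.gait)
        weight = normalized_weight(n_hat, grid)
        forces[j], torques[j] = net_force_torque(config, weight, traj.env)
    t = traj.times[idx]
    span = t[-1] - t[0]
    f_avg = np.trapezoid(forces, t, axis=0) / span
    t_avg = np.trapezoid(torques, t) / span
    return f_avg, float(t_avg)


def acceleration(
    state: SnakeState,
    gait: GaitParams,
    env: EnvironmentParams,
    grid: BodyGrid,
) -> tuple[np.ndarray, float]:
    """COM and angular acceleration ``(x_bar_tt, alpha_bar_tt)`` at one instant."""
    t = state.time
    s = grid.s_values
    config = reconstruct_configuration(state, gait, grid, t)

    n_hat = lifting_modulation(s, t, gait)
    weight = normalized_weight(n_hat, grid)
    force = friction_force_density(config, weight, env)

    f_net = grid.quad_weights @ force
    com_acc = f_net / env.froude

    torque = float(grid.integrate(_cross_z(config.centered(), force)))
    J = moment_of_inertia(config, grid)

    kappa_t, kappa_tt = curvature_time_derivatives(s, t, gait)
    alpha_t = state.alpha_bar_t + mean_zero_integral(kappa_t, grid)
    I_t = mean_zero_integral(config.tangents.T, grid)  # (2, n_s)
    I_n = mean_zero_integral(config.normals.T, grid)
    I_t_at2 = mean_zero_integral(config.tangents.T * alpha_t**2, grid)
    I_t_ktt = mean_zero_integral(config.tangents.T * mean_zero_integral(kappa_tt, grid), grid)
    correction = float(grid.integrate(np.sum(I_n * I_t_at2 - I_t * I_t_ktt, axis=0)))

    alpha_acc = torque / (env.froude * J) + correction / J

    if not (np.isfinite(com_acc).all() and np.isfinite(alpha_acc)):
        raise FloatingPointError(
            f"non-finite acceleration at t={t}: com_acc={com_acc}, alpha_acc={alpha_acc}"
        )
    return com_acc, alpha_acc


def simulate(
    gait: GaitParams,
    env: EnvironmentParams,
    sim: SimConfig | None = None,
    initial: SnakeState | None = None,
) -> Trajectory:
    """Integrate the reduced dynamics over ``sim.n_periods`` undulation periods.

    The snake is released from rest with the wave already imposed at t = 0;
    startup transients are left to die out and excluded by taking metrics over
    a trailing window (the 10-period protocol).  Fully deterministic.
    """
    sim = sim or SimConfig()
    initial = initial or SnakeState()
    grid = sim.make_grid()

    uniform = env.friction_map is None or env.friction_map.is_uniform
    if uniform and _kernels.HAVE_NUMBA:
        lift_code = {"cosine": _kernels.LIFT_COSINE, "exp_curvature": _kernels.LIFT_EXP, "none": _kernels.LIFT_NONE}[
            gait.lifting_model
        ]
        s, w = grid.s_values, grid.quad_weights
        args = (
            s, w, gait.epsilon, gait.k, gait.A, gait.phi, gait.k_l, lift_code,
            env.mu_t_ratio, env.mu_b_ratio, env.froude, env.velocity_reg,
        )

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            return _kernels.rhs_uniform(t, y, *args)

    else:

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            state = SnakeState.from_vector(y, t)
            com_acc, alpha_acc = acceleration(state, gait, env, grid)
            return np.array([y[2], y[3], com_acc[0], com_acc[1], y[5], alpha_acc])

    t0 = initial.time
    t1 = t0 + sim.n_periods
    n_out = int(round(sim.n_periods * sim.samples_per_period)) + 1
    t_eval = np.linspace(t0, t1, n_out)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        initial.as_vector(),
        method="RK45",
        rtol=sim.rtol,
        atol=sim.atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if sol.t.size else t0}: {sol.message}; "
            f"last state={sol.y[:, -1] if sol.y.size else initial.as_vector()}"
        )
    return Trajectory(times=sol.t, states=sol.y.T, gait=gait, env=env, sim=sim)


def write_trajectory(traj: Trajectory, csv_path, meta_path=None) -> None:
    """CSV time series (%.12g) with a JSON metadata sidecar."""
    df = traj.to_frame()
    df.to_csv(csv_path, index=False, float_format="%.12g")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump(traj.metadata(), fh, indent=2)
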