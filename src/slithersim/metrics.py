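"""Steady-state gait metrics and behavior classification.

Three scalars summarise a steady gait over an averaging window of at least one
undulation period:

* pose angle ``gamma``: period average of the signed angle
  ``arctan2((t_bar x u_bar) . e_z, t_bar . u_bar)`` between the mean body
  orientation ``t_bar = (cos alpha_bar, sin alpha_bar)`` and the COM velocity
  direction — near 0 for slithering, large for sidewinding, near pi for
  backward travel;
* steering rate ``theta_dot``: net rotation rate of the COM trajectory
  heading, zero for rectilinear travel;
* effective speed ``|v_eff|``: magnitude of the window-averaged COM velocity
  expressed in the frame co-rotating at ``theta_dot`` (net progress per
  period, in body lengths).

The trajectory heading is taken from the one-period trailing average of the
COM velocity, which filters the within-period wobble of undulatory motion; a
directionality guard keeps the metrics finite and meaningful when the COM
merely oscillates in place (no net travel).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "BehaviorLabel",
    "ClassifierConfig",
    "GaitMetrics",
    "pose_angle",
    "steering_rate",
    "effective_speed",
    "compute_metrics",
    "classify",
]


class BehaviorLabel(str, enum.Enum):
    STRAIGHT_SLITHERING = "straight_slithering"
    TURNING_SLITHERING = "turning_slithering"
    STRAIGHT_SIDEWINDING = "straight_sidewinding"
    TURNING_SIDEWINDING = "turning_sidewinding"
    SPINNING = "spinning"
    BACKWARD_SLITHERING = "backward_slithering"
    TRANSITION = "transition"

    def __str__(self) -> str:  # plain value in CSV/log output
        return self.value


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds mapping (gamma, theta_dot, v_eff) to behavior labels.

    The published phase diagrams do not print their cutoffs; these defaults
    reproduce the qualitative phase topology and are surfaced in all output
    metadata.  Angles in radians, rates in rad/period, speeds in body
    lengths/period.
    """

    straight_max_steering: float = 0.05
    sidewinding_min_pose: float = 0.35
    backward_min_pose: float = 2.6
    spinning_max_speed: float = 0.02
    # steady-state convergence: max change between successive one-period windows
    converge_d_steering: float = 0.05
    converge_d_pose: float = 0.1
    converge_d_speed: float = 0.02
    # heading is meaningless when net travel is this small a fraction of path length
    min_directionality: float = 0.1

    def __post_init__(self) -> None:
        if min(self.straight_max_steering, self.sidewinding_min_pose, self.spinning_max_speed) <= 0:
            raise ValueError("classifier thresholds must be positive")
        if not self.sidewinding_min_pose < self.backward_min_pose:
            raise ValueError("sidewinding and backward pose bands must not overlap")


@dataclass
class GaitMetrics:
    """Steady-state summary of one simulated gait."""

    gamma: float
    theta_dot: float
    v_eff: float
    directional: bool = True
    converged: bool = True
    label: BehaviorLabel | None = None


def _wrap_angle(x: float) -> float:
    """Wrap to (-pi, pi]."""
    w = (x + np.pi) % (2.0 * np.pi) - np.pi
    return np.pi if w == -np.pi else float(w)


def _window_samples(traj: Trajectory, window):
    window = window or traj.default_window()
    idx = traj.window_slice(window)
    return idx, traj.times[idx], traj.com_vel[idx]


def _directionality(t: np.ndarray, v: np.ndarray) -> float:
    disp = np.trapezoid(v, t, axis=0)
    path = float(np.trapezoid(np.linalg.norm(v, axis=1), t))
    if path <= 1e-300:
        return 0.0
    return float(np.linalg.norm(disp) / path)


def _smoothed_velocity(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    """Trailing one-period moving average of the COM velocity at the window samples.

    Falls back to the instantaneous velocity when the trajectory does not
    extend a full period before the window (e.g. synthetic fixtures).
    """
    t_all = traj.times
    t_win = t_all[idx]
    if t_win[0] - 1.0 < t_all[0] - 1e-9:
        return traj.com_vel[idx]
    cum = np.concatenate(
        [np.zeros((1, 2)), np.cumsum(0.5 * (traj.com_vel[1:] + traj.com_vel[:-1]) * np.diff(t_all)[:, None], axis=0)]
    )
    lead = np.stack([np.interp(t_win, t_all, cum[:, j]) for j in range(2)], axis=1)
    lag = np.stack([np.interp(t_win - 1.0, t_all, cum[:, j]) for j in range(2)], axis=1)
    return lead - lag


def steering_rate(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    cfg: ClassifierConfig | None = None,
) -> float:
    """Net heading rotation of the COM trajectory per period over the window."""
    cfg = cfg or ClassifierConfig()
    idx, t, v = _window_samples(traj, window)
    if _directionality(t, v) < cfg.min_directionality:
        return 0.0
    vs = _smoothed_velocity(traj, idx)
    heading = np.unwrap(np.arctan2(vs[:, 1], vs[:, 0]))
    return float((heading[-1] - heading[0]) / (t[-1] - t[0]))


def pose_angle(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
) -> float:
    """Period-averaged signed angle between body orientation and travel direction."""
    idx, t, v = _window_samples(traj, window)
    alpha = traj.alpha_bar[idx]
    t_bar = np.stack([np.cos(alpha), np.sin(alpha)], axis=1)
    cross = t_bar[:, 0] * v[:, 1] - t_bar[:, 1] * v[:, 0]
    dot = np.einsum("ij,ij->i", t_bar, v)
    phi = np.unwrap(np.arctan2(cross, dot))
    mean = float(np.trapezoid(phi, t) / (t[-1] - t[0]))
    return _wrap_angle(mean)


def effective_speed(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    theta_dot: float | None = None,
    cfg: ClassifierConfig | None = None,
) -> float:
    """Window-averaged COM speed in the co-rotating frame (net progress rate)."""
    idx, t, v = _window_samples(traj, window)
    if theta_dot is None:
        theta_dot = steering_rate(traj, window, cfg)
    ang = -theta_dot * (t - 0.5 * (t[0] + t[-1]))
    c, s = np.cos(ang), np.sin(ang)
    v_rot = np.stack([c * v[:, 0] - s * v[:, 1], s * v[:, 0] + c * v[:, 1]], axis=1)
    mean = np.trapezoid(v_rot, t, axis=0) / (t[-1] - t[0])
    return float(np.linalg.norm(mean))


def compute_metrics(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    cfg: ClassifierConfig | None = None,
) -> GaitMetrics:
    """All three gait metrics plus convergence/directionality diagnostics.

    Convergence compares the metrics over the requested window with the same
    metrics one window earlier; a gait still evolving is flagged (and later
    classified as transitional).
    """
    cfg = cfg or ClassifierConfig()
    window = window or traj.default_window()
    idx, t, v = _window_samples(traj, window)
    directional = _directionality(t, v) >= cfg.min_directionality

    th = steering_rate(traj, window, cfg)
    g = pose_angle(traj, window)
    vv = effective_speed(traj, window, theta_dot=th)

    converged = True
    span = window[1] - window[0]
    prev = (window[0] - span, window[0])
    if prev[0] >= traj.times[0] - 1e-9:
        th0 = steering_rate(traj, prev, cfg)
        g0 = pose_angle(traj, prev)
        vv0 = effective_speed(traj, prev, theta_dot=th0)
        converged = (
            abs(th - th0) <= cfg.converge_d_steering
            and abs(_wrap_angle(g - g0)) <= cfg.converge_d_pose
            and abs(vv - vv0) <= cfg.converge_d_speed
        )

    metrics = GaitMetrics(gamma=g, theta_dot=th, v_eff=vv, directional=directional, converged=converged)
    metrics.label = classify(metrics, cfg)
    return metrics


def classify(metrics: GaitMetrics, cfg: ClassifierConfig | None = None) -> BehaviorLabel:
    """Deterministic behavior label from the three steady-state metrics."""
    cfg = cfg or ClassifierConfig()
    if not metrics.converged:
        return BehaviorLabel.TRANSITION
    straight = abs(metrics.theta_dot) < cfg.straight_max_steering
    if metrics.v_eff < cfg.spinning_max_speed and not straight:
        return BehaviorLabel.SPINNING
    g = abs(metrics.gamma)
    if g > cfg.backward_min_pose:
        return BehaviorLabel.BACKWARD_SLITHERING
    if g >= cfg.sidewinding_min_pose:
        return BehaviorLabel.STRAIGHT_SIDEWINDING if straight else BehaviorLabel.TURNING_SIDEWINDING
    return BehaviorLabel.STRAIGHT_SLITHERING if straight else BehaviorLabel.TURNING_SLITHERING
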