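"""Body waves and planar shape reconstruction.

A snake is idealised as an inextensible planar curve of unit (nondimensional)
length, arclength ``s`` running from tail (0) to head (1), with a prescribed
lateral-curvature traveling wave

    kappa(s, t) = eps * cos(2*pi*k*(s + t))

and a lifting wave that redistributes body weight along the arclength,

    N_hat(s, t) = max{0, A * cos(2*pi*k_l*(s + t + Phi)) + 1},    k_l = lam * k.

Shape follows from curvature through the mean-zero integration operator
``I[f](s) = int_0^s f ds' - <int_0^s f ds'>``: the local orientation is
``alpha = alpha_bar + I[kappa]`` and the local position is
``x = x_bar + I[t_hat]``, which pins the quadrature mean of the shape to the
centre of mass by construction.  All lengths are in body lengths, all times in
undulation periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "GaitParams",
    "BodyGrid",
    "BodyConfiguration",
    "lateral_curvature",
    "curvature_time_derivatives",
    "lifting_modulation",
    "mean_zero_integral",
    "reconstruct_configuration",
]

_TWO_PI = 2.0 * np.pi

LIFTING_MODELS = ("cosine", "exp_curvature", "none")


@dataclass(frozen=True)
class GaitParams:
    """Actuation template: lateral and lifting traveling waves.

    Parameters
    ----------
    epsilon : float
        Lateral curvature amplitude (dimensionless; body-length/period units).
    k : float
        Lateral wavenumber, waves per body length.  Must be positive.
    A : float
        Lifting amplitude; may be negative (lifts the other side).
    phi : float
        Lifting phase offset Phi as a fraction of a period, in [0, 1).
    lam : float
        Ratio of lifting to lateral wavenumber, ``k_l = lam * k``.
        ``lam = 1`` lifts one side only (sidewinding template), ``lam = 2``
        lifts both sides symmetrically.
    lifting_model : str
        One of ``cosine`` (default), ``exp_curvature`` (weight ~ exp(-kappa),
        provided for comparison) or ``none`` (uniform weight).
    """

    epsilon: float = 7.0
    k: float = 1.0
    A: float = 0.0
    phi: float = 0.0
    lam: float = 1.0
    lifting_model: str = "cosine"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"wavenumber k must be > 0, got {self.k}")
        if self.lam < 0:
            raise ValueError(f"wavenumber ratio lam must be >= 0, got {self.lam}")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phase offset phi must lie in [0, 1), got {self.phi}")
        if self.lifting_model not in LIFTING_MODELS:
            raise ValueError(
                f"lifting_model must be one of {LIFTING_MODELS}, got {self.lifting_model!r}"
            )

    @property
    def k_l(self) -> float:
        """Lifting wavenumber."""
        return self.lam * self.k

    def replace(self, **changes) -> "GaitParams":
        return replace(self, **changes)


def _trapezoid_weights(n: int) -> np.ndarray:
    w = np.full(n, 1.0 / (n - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


@dataclass(frozen=True)
class BodyGrid:
    """Uniform arclength grid on [0, 1] with trapezoidal quadrature weights."""

    n_s: int = 201
    s_values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    quad_weights: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_s < 3:
            raise ValueError(f"grid needs at least 3 nodes, got {self.n_s}")
        if self.s_values is None:
            object.__setattr__(self, "s_values", np.linspace(0.0, 1.0, self.n_s))
        if self.quad_weights is None:
            object.__setattr__(self, "quad_weights", _trapezoid_weights(self.n_s))
        s = self.s_values
        if s[0] != 0.0 or s[-1] != 1.0 or np.any(np.diff(s) <= 0):
            raise ValueError("s_values must increase strictly from 0 to 1")
        if abs(self.quad_weights.sum() - 1.0) > 1e-12:
            raise ValueError("quadrature weights must sum to 1")

    def integrate(self, f: np.ndarray) -> np.ndarray | float:
        """Quadrature of samples over s in [0, 1] (last axis = nodes)."""
        return f @ self.quad_weights


@dataclass
class BodyConfiguration:
    """Planar body shape and its time derivative at one instant.

    ``positions`` and ``velocities`` have shape ``(n_s, 2)``; ``orientations``,
    ``tangents``, ``normals`` follow the usual planar frame with the normal
    obtained by rotating the tangent by +90 degrees.
    """

    grid: BodyGrid
    time: float
    positions: np.ndarray
    orientations: np.ndarray
    tangents: np.ndarray
    normals: np.ndarray
    velocities: np.ndarray

    @property
    def com(self) -> np.ndarray:
        return self.grid.quad_weights @ self.positions

    def centered(self) -> np.ndarray:
        """Positions relative to the centre of mass, ``x - x_bar``."""
        return self.positions - self.com

    def to_frame(self):
        """Per-node table (s, x, y, alpha, vx, vy) as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "s": self.grid.s_values,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "alpha": self.orientations,
                "vx": self.velocities[:, 0],
                "vy": self.velocities[:, 1],
            }
        )


def lateral_curvature(s, t, gait: GaitParams):
    """Lateral curvature wave ``eps * cos(2 pi k (s + t))``."""
    return gait.epsilon * np.cos(_TWO_PI * gait.k * (np.asarray(s) + t))


def curvature_time_derivatives(s, t, gait: GaitParams):
    """First and second time derivatives of the lateral curvature wave."""
    phase = _TWO_PI * gait.k * (np.asarray(s) + t)
    w = _TWO_PI * gait.k
    kappa_t = -w * gait.epsilon * np.sin(phase)
    kappa_tt = -(w**2) * gait.epsilon * np.cos(phase)
    return kappa_t, kappa_tt


def lifting_modulation(s, t, gait: GaitParams):
    """Unnormalised weight-redistribution wave ``N_hat(s, t) >= 0``.

    The clipping at zero prevents unphysical negative weight; for the
    ``exp_curvature`` model the proportionality constant is irrelevant because
    the weight is normalised downstream.
    """
    s = np.asarray(s, dtype=float)
    if gait.lifting_model == "none":
        return np.ones_like(s)
    if gait.lifting_model == "exp_curvature":
        return np.exp(-lateral_curvature(s, t, gait))
    raw = gait.A * np.cos(_TWO_PI * gait.k_l * (s + t + gait.phi)) + 1.0
    return np.maximum(0.0, raw)


def mean_zero_integral(f: np.ndarray, grid: BodyGrid) -> np.ndarray:
    """Mean-zero running integral ``I[f]`` sampled on the grid.

    Cumulative trapezoid from s = 0 followed by subtraction of its quadrature
    mean, which makes the zero-mean property exact by construction.  Works on
    the last axis, so vector fields of shape ``(2, n_s)`` pass through
    componentwise.
    """
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != grid.n_s:
        raise ValueError("sample count does not match grid")
    g = cumulative_trapezoid(f, grid.s_values, axis=-1, initial=0.0)
    return g - (g @ grid.quad_weights)[..., None]


def reconstruct_configuration(state, gait: GaitParams, grid: BodyGrid, t: float | None = None) -> BodyConfiguration:
    """Rebuild the planar body and its velocity field from the reduced state.

    The state supplies the centre of mass, mean orientation and their time
    derivatives; curvature supplies everything else through ``I[.]``.  Node
    velocities are assembled analytically by the chain rule,
    ``x_t = x_bar_t + I[alpha_t * n]`` with ``alpha_t = alpha_bar_t + I[kappa_t]``,
    rather than by numerical differencing.
    """
    if t is None:
        t = state.time
    s = grid.s_values
    kappa = lateral_curvature(s, t, gait)
    alpha = state.alpha_bar + mean_zero_integral(kappa, grid)
    c, sn = np.cos(alpha), np.sin(alpha)
    tangents = np.stack([c, sn], axis=-1)
    normals = np.stack([-sn, c], axis=-1)
    positions = state.com + mean_zero_integral(tangents.T, grid).T

    kappa_t, _ = curvature_time_derivatives(s, t, gait)
    alpha_t = state.alpha_bar_t + mean_zero_integral(kappa_t, grid)
    velocities = state.com_vel + mean_zero_integral((alpha_t * normals.T), grid).T

    return BodyConfiguration(
        grid=grid,
        time=t,
        positions=positions,
        orientations=alpha,
        tangents=tangents,
        normals=normals,
        velocities=velocities,
    )
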