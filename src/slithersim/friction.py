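"""Anisotropic Coulomb friction with weight redistribution and friction maps.

The substrate acts on each body point through a Coulomb force density
``F(s, t) = -N(s, t) * mu(s, t)``, where ``N`` is the normalised weight
distribution and ``mu`` decomposes the (regularised) sliding direction ``u``
into transverse and fore/aft components:

    mu = (mu_t/mu_f) (u . n) n + [H(u . t) + (mu_b/mu_f) (1 - H(u . t))] (u . t) t

with ``H`` the Heaviside step (H(0) = 1/2), so backward sliding sees the
(typically larger) backward coefficient.  Forces are scaled by ``rho g mu_f``,
which leaves the ratios ``mu_t/mu_f`` and ``mu_b/mu_f`` and the Froude number
``Fr = (L / tau^2) / (g mu_f)`` as the only environmental parameters.

Heterogeneous substrates are described by a :class:`FrictionMap`: a list of
geometric primitives (disks, strips, radial gradients, rasters), each scaling
the whole friction vector by a positive factor ``p`` inside its footprint,
with background scale 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import BodyConfiguration, BodyGrid

__all__ = [
    "EnvironmentParams",
    "FrictionMap",
    "Disk",
    "Strip",
    "RadialGradient",
    "Raster",
    "froude_number",
    "regularized_direction",
    "friction_coefficient_vector",
    "normalized_weight",
    "local_scale",
    "friction_force_density",
]


def froude_number(length: float, period: float, g: float, mu_f: float) -> float:
    """Froude number ``Fr = (L / tau^2) / (g mu_f)``, inertia over friction."""
    return (length / period**2) / (g * mu_f)


# --------------------------------------------------------------------------
# friction map primitives

@dataclass(frozen=True)
class Disk:
    """Circular patch of uniform friction scale ``p``."""

    center: tuple[float, float]
    diameter: float
    scale: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        return np.einsum("ij,ij->i", d, d) <= (0.5 * self.diameter) ** 2

    def scale_at(self, pts: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return np.full(mask.sum(), self.scale)


@dataclass(frozen=True)
class Strip:
    """Infinite band of width ``w``; ``scale = 0`` models a frictionless strip."""

    anchor: tuple[float, float]
    angle: float  # direction of the strip axis, radians
    width: float
    scale: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        n = np.array([-np.sin(self.angle), np.cos(self.angle)])
        dist = (pts - np.asarray(self.anchor)) @ n
        return np.abs(dist) <= 0.5 * self.width

    def scale_at(self, pts: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return np.full(mask.sum(), self.scale)


@dataclass(frozen=True)
class RadialGradient:
    """Lens-like patch whose scale interpolates from ``scale`` at the centre to 1 at the rim."""

    center: tuple[float, float]
    diameter: float
    scale: float
    profile: str = "linear"

    def __post_init__(self) -> None:
        if self.profile not in ("linear", "quadratic"):
            raise ValueError(f"unknown radial profile {self.profile!r}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        return np.einsum("ij,ij->i", d, d) <= (0.5 * self.diameter) ** 2

    def scale_at(self, pts: np.ndarray, mask: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(pts[mask] - np.asarray(self.center), axis=-1)
        frac = r / (0.5 * self.diameter)
        if self.profile == "quadratic":
            frac = frac**2
        return self.scale + (1.0 - self.scale) * frac


@dataclass(frozen=True)
class Raster:
    """Gridded scale field with nearest-cell lookup; outside the extent -> 1."""

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray  # shape (ny, nx), row i is y = origin_y + i*cell

    def contains(self, pts: np.ndarray) -> np.ndarray:
        ny, nx = np.asarray(self.values).shape
        rel = (pts - np.asarray(self.origin)) / self.cell_size
        return (
            (rel[:, 0] >= 0)
            & (rel[:, 0] < nx)
            & (rel[:, 1] >= 0)
            & (rel[:, 1] < ny)
        )

    def scale_at(self, pts: np.ndarray, mask: np.ndarray) -> np.ndarray:
        vals = np.asarray(self.values)
        rel = (pts[mask] - np.asarray(self.origin)) / self.cell_size
        ix = np.clip(rel[:, 0].astype(int), 0, vals.shape[1] - 1)
        iy = np.clip(rel[:, 1].astype(int), 0, vals.shape[0] - 1)
        return vals[iy, ix]


@dataclass(frozen=True)
class FrictionMap:
    """Ordered collection of friction primitives over a background scale of 1.

    On overlap the last-listed primitive wins, which keeps lookup
    deterministic.  Scales must be non-negative (0 = frictionless).
    """

    primitives: tuple = ()

    def __post_init__(self) -> None:
        for p in self.primitives:
            low = np.asarray(p.values).min() if isinstance(p, Raster) else p.scale
            if low < 0:
                raise ValueError("friction scales must be >= 0")

    @property
    def is_uniform(self) -> bool:
        return len(self.primitives) == 0

    def scale_at(self, points: np.ndarray) -> np.ndarray:
        """Friction scale at an ``(n, 2)`` array of lab positions."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.ones(pts.shape[0])
        for prim in self.primitives:  # later primitives overwrite earlier ones
            mask = prim.contains(pts)
            if mask.any():
                out[mask] = prim.scale_at(pts, mask)
        return out


def local_scale(point, friction_map: FrictionMap | None) -> float | np.ndarray:
    """Scalar convenience wrapper around :meth:`FrictionMap.scale_at`."""
    if friction_map is None:
        return 1.0 if np.ndim(point) == 1 else np.ones(np.shape(point)[0])
    out = friction_map.scale_at(point)
    return float(out[0]) if np.ndim(point) == 1 else out


# --------------------------------------------------------------------------
# environment

@dataclass(frozen=True)
class EnvironmentParams:
    """Frictional environment of a run.

    ``mu_t_ratio`` (transverse/forward) is the key parameter selecting between
    gait regimes; ``mu_b_ratio`` defaults to the measured 1.5 and matters
    little.  ``froude`` defaults to 0.1 (friction-dominated).  ``velocity_reg``
    is the Coulomb regularisation scale delta in body lengths per period.
    """

    mu_t_ratio: float = 2.0
    mu_b_ratio: float = 1.5
    froude: float = 0.1
    velocity_reg: float = 1e-6
    friction_map: FrictionMap | None = None

    def __post_init__(self) -> None:
        if self.mu_t_ratio <= 0 or self.mu_b_ratio <= 0:
            raise ValueError("friction ratios must be > 0")
        if self.froude <= 0:
            raise ValueError("Froude number must be > 0")
        if self.velocity_reg <= 0:
            raise ValueError("velocity regularization must be > 0")


# --------------------------------------------------------------------------
# pointwise operations

def regularized_direction(v: np.ndarray, delta: float) -> np.ndarray:
    """Smoothed Coulomb direction ``u = v / sqrt(|v|^2 + delta^2)``.

    Bounded by 1, tends to ``v/|v|`` for fast sliding and vanishes smoothly at
    rest, removing the singularity of the raw unit vector.  Accepts a single
    2-vector or an ``(n, 2)`` stack.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    v = np.asarray(v, dtype=float)
    speed2 = np.sum(v * v, axis=-1, keepdims=True)
    return v / np.sqrt(speed2 + delta**2)


def friction_coefficient_vector(
    u: np.ndarray,
    t_hat: np.ndarray,
    n_hat: np.ndarray,
    env: EnvironmentParams,
    *,
    check_frame: bool = True,
) -> np.ndarray:
    """Direction-resolved friction coefficient vector (in units of mu_f)."""
    u = np.asarray(u, dtype=float)
    t_hat = np.asarray(t_hat, dtype=float)
    n_hat = np.asarray(n_hat, dtype=float)
    if check_frame:
        if (
            np.abs(np.sum(t_hat * t_hat, axis=-1) - 1.0).max() > 1e-9
            or np.abs(np.sum(n_hat * n_hat, axis=-1) - 1.0).max() > 1e-9
            or np.abs(np.sum(t_hat * n_hat, axis=-1)).max() > 1e-9
        ):
            raise ValueError("t_hat, n_hat must be unit and orthogonal")
    un = np.sum(u * n_hat, axis=-1, keepdims=True)
    ut = np.sum(u * t_hat, axis=-1, keepdims=True)
    heav = 0.5 * (1.0 + np.sign(ut))
    fore_aft = heav + env.mu_b_ratio * (1.0 - heav)
    return env.mu_t_ratio * un * n_hat + fore_aft * ut * t_hat


def normalized_weight(n_hat_samples: np.ndarray, grid: BodyGrid) -> np.ndarray:
    """Normalise the lifting wave so the body's total weight is conserved.

    Returns ``N = eta * N_hat`` with ``eta = 1 / int_0^1 N_hat ds``; a lifting
    wave that removes (almost) all weight is degenerate and rejected.
    """
    n_hat_samples = np.asarray(n_hat_samples, dtype=float)
    if n_hat_samples.min() < 0:
        raise ValueError("N_hat must be non-negative")
    total = float(grid.integrate(n_hat_samples))
    if total <= 1e-12:
        raise ValueError("degenerate lifting wave: N_hat integrates to ~0 (whole body lifted)")
    return n_hat_samples / total


def friction_force_density(
    config: BodyConfiguration,
    weight: np.ndarray,
    env: EnvironmentParams,
) -> np.ndarray:
    """Per-node friction force density ``F(s) = -N(s) p(x(s)) mu(u, t, n)``."""
    u = regularized_direction(config.velocities, env.velocity_reg)
    mu = friction_coefficient_vector(u, config.tangents, config.normals, env, check_frame=False)
    scale = np.asarray(weight, dtype=float)[:, None] * mu
    if env.friction_map is not None and not env.friction_map.is_uniform:
        scale = scale * env.friction_map.scale_at(config.positions)[:, None]
    return -scale
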