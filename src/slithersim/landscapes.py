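"""Heterogeneous friction landscapes and passive-deflection experiments.

Substrate features — rows of high-friction patches standing in for rigid
posts, frictionless strips, gradient "lenses", arbitrary rasters — enter the
planar model purely as a multiplicative scaling field on the local friction
coefficients.  A snake slithering across such a landscape is passively
deflected; the experiments here measure the deflection angle ``alpha_p``
(exit heading minus entry heading) over deterministic ensembles of initial
lateral offsets, the planar analogue of the optics-style demonstrations
(diffraction through a post row, refraction/reflection at a strip).

Everything is deterministic: the spread of deflections comes from where each
snake meets the pattern, not from noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinematics import GaitParams, reconstruct_configuration
from .friction import Disk, FrictionMap, RadialGradient, Raster, Strip, EnvironmentParams
from .dynamics import SimConfig, SnakeState, Trajectory, simulate

__all__ = ["EnsembleSpec", "DeflectionResult", "build_map", "run_ensemble", "incidence_scan"]

_PRIMITIVES = {
    "disk": Disk,
    "strip": Strip,
    "radial_gradient": RadialGradient,
    "raster": Raster,
}


def build_map(primitive_specs: list[dict]) -> FrictionMap:
    """Assemble a :class:`FrictionMap` from a list of primitive specs.

    Each spec is a mapping with a ``type`` key (``disk``, ``strip``,
    ``radial_gradient`` or ``raster``) plus that primitive's numeric fields,
    e.g. ``{"type": "disk", "center": [3, 0], "diameter": 0.5, "scale": 50}``.
    Later-listed primitives win on overlap.
    """
    prims = []
    for spec in primitive_specs:
        spec = dict(spec)
        kind = spec.pop("type", None)
        if kind not in _PRIMITIVES:
            raise ValueError(f"unknown friction primitive type {kind!r}")
        cls = _PRIMITIVES[kind]
        if kind == "raster":
            spec["values"] = np.asarray(spec["values"], dtype=float)
        if "center" in spec:
            spec["center"] = tuple(spec["center"])
        if "anchor" in spec:
            spec["anchor"] = tuple(spec["anchor"])
        if "origin" in spec:
            spec["origin"] = tuple(spec["origin"])
        prims.append(cls(**spec))
    return FrictionMap(primitives=tuple(prims))


def post_row(
    count: int = 7,
    spacing: float = 1.0,
    diameter: float = 0.5,
    scale: float = 50.0,
    x: float = 4.0,
    center_y: float = 0.0,
) -> FrictionMap:
    """Row of equally spaced high-friction disks (posts reduced to patches)."""
    ys = center_y + (np.arange(count) - (count - 1) / 2.0) * spacing
    return FrictionMap(
        primitives=tuple(Disk(center=(x, float(y)), diameter=diameter, scale=scale) for y in ys)
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """Deterministic ensemble of snakes launched at different lateral offsets."""

    offsets: tuple = ()
    friction_map: FrictionMap = field(default_factory=FrictionMap)
    gait: GaitParams = field(default_factory=lambda: GaitParams(A=0.0, lifting_model="none"))
    env: EnvironmentParams = field(default_factory=lambda: EnvironmentParams(mu_t_ratio=10.0))
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_periods=12))
    heading: float = 0.0  # initial mean orientation, radians
    start: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.offsets) < 1:
            raise ValueError("ensemble needs at least one offset")

    @classmethod
    def evenly_spaced(cls, count: int, lo: float, hi: float, **kwargs) -> "EnsembleSpec":
        return cls(offsets=tuple(np.linspace(lo, hi, count)), **kwargs)

    @property
    def count(self) -> int:
        return len(self.offsets)


@dataclass
class DeflectionResult:
    """Per-snake deflection angles and traversal outcomes."""

    offsets: np.ndarray
    alpha_p: np.ndarray  # radians, NaN where stuck
    stuck: np.ndarray  # bool
    entry_heading: np.ndarray
    exit_heading: np.ndarray

    @property
    def n_stuck(self) -> int:
        return int(self.stuck.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "alpha_p": self.alpha_p,
                "entry_heading": self.entry_heading,
                "exit_heading": self.exit_heading,
                "stuck": self.stuck,
            }
        )

    def pdf(self, bin_width_deg: float = 5.0) -> pd.DataFrame:
        """Binned probability density of the deflection angle, in degrees.

        Stuck snakes are excluded from (but not hidden by) the density; the
        density integrates to 1 over the (-90, 90] degree support whenever any
        snake traversed.
        """
        edges = np.arange(-90.0, 90.0 + bin_width_deg, bin_width_deg)
        vals = np.degrees(self.alpha_p[~self.stuck])
        counts, _ = np.histogram(vals, bins=edges)
        total = counts.sum()
        density = counts / (total * bin_width_deg) if total else np.zeros_like(counts, dtype=float)
        return pd.DataFrame(
            {"bin_left_deg": edges[:-1], "bin_right_deg": edges[1:], "pdf_per_deg": density, "count": counts}
        )


def _wrap(x: float) -> float:
    w = (x + np.pi) % (2.0 * np.pi) - np.pi
    return np.pi if w == -np.pi else float(w)


def _window_heading(traj: Trajectory, t0: float, t1: float) -> float:
    """Travel direction as the heading of the COM displacement over [t0, t1]."""
    x0 = np.array([np.interp(t0, traj.times, traj.com[:, j]) for j in range(2)])
    x1 = np.array([np.interp(t1, traj.times, traj.com[:, j]) for j in range(2)])
    d = x1 - x0
    return float(np.arctan2(d[1], d[0]))


def _interaction_span(traj: Trajectory, fmap: FrictionMap) -> tuple[float, float] | None:
    """First and last sampled times at which any body node sees scale != 1."""
    if fmap.is_uniform:
        return None
    grid = traj.sim.make_grid()
    hit_times = []
    for i in range(traj.times.size):
        config = reconstruct_configuration(traj.state_at(i), traj.gait, grid)
        if np.any(fmap.scale_at(config.positions) != 1.0):
            hit_times.append(traj.times[i])
    if not hit_times:
        return None
    return float(hit_times[0]), float(hit_times[-1])


def _deflection(traj: Trajectory, fmap: FrictionMap, settle: float = 2.0):
    """Entry/exit headings and deflection for one run; returns (a_in, a_out, alpha_p, stuck)."""
    t_end = float(traj.times[-1])
    span = _interaction_span(traj, fmap)
    if span is None:
        # never touched the pattern: compare post-transient and final headings
        a_in = _window_heading(traj, settle, settle + 1.0)
        a_out = _window_heading(traj, t_end - 1.0, t_end)
        return a_in, a_out, _wrap(a_out - a_in), False
    t_first, t_last = span
    entry_t0 = max(t_first - 1.0, settle)
    if entry_t0 + 1.0 > t_first + 0.5:  # hit the pattern before settling
        entry_t0 = max(t_first - 1.0, 0.0)
    a_in = _window_heading(traj, entry_t0, entry_t0 + 1.0)
    if t_last + 1.0 > t_end + 1e-9:
        return a_in, np.nan, np.nan, True  # still interacting at sim end
    a_out = _window_heading(traj, t_last, t_last + 1.0)
    # a snake that barely moves after the interaction is stuck, not deflected
    x_last = np.array([np.interp(t_last, traj.times, traj.com[:, j]) for j in range(2)])
    x_end = traj.com[-1]
    if np.linalg.norm(x_end - x_last) < 0.05 * (t_end - t_last):
        return a_in, a_out, np.nan, True
    return a_in, a_out, _wrap(a_out - a_in), False


def run_ensemble(spec: EnsembleSpec, progress: bool = False) -> DeflectionResult:
    """Run every ensemble member and measure its passive deflection."""
    env = replace(spec.env, friction_map=spec.friction_map)
    n = spec.count
    alpha_p = np.full(n, np.nan)
    stuck = np.zeros(n, dtype=bool)
    a_in = np.full(n, np.nan)
    a_out = np.full(n, np.nan)
    items = list(enumerate(spec.offsets))
    if progress:
        from tqdm import tqdm

        items = tqdm(items, desc="ensemble")
    lateral = np.array([-np.sin(spec.heading), np.cos(spec.heading)])
    for i, off in items:
        com0 = np.asarray(spec.start, dtype=float) + float(off) * lateral
        init = SnakeState(com=com0, alpha_bar=spec.heading)
        traj = simulate(spec.gait, env, spec.sim, init)
        a_in[i], a_out[i], alpha_p[i], stuck[i] = _deflection(traj, spec.friction_map)
    return DeflectionResult(
        offsets=np.asarray(spec.offsets, dtype=float),
        alpha_p=alpha_p,
        stuck=stuck,
        entry_heading=a_in,
        exit_heading=a_out,
    )


def incidence_scan(
    strip: Strip,
    incidence_angles,
    gait: GaitParams | None = None,
    env: EnvironmentParams | None = None,
    sim: SimConfig | None = None,
    approach_distance: float = 4.0,
) -> pd.DataFrame:
    """Refraction/reflection outcomes of a snake crossing a friction strip.

    For each incidence angle ``alpha`` (measured from the strip normal) a
    snake is aimed at the strip axis from ``approach_distance`` body lengths
    away.  The outcome is ``reflected`` when the exit heading's component
    along the strip normal reverses relative to entry, ``refracted``
    otherwise; whether reflection sets in at grazing incidence is recorded in
    the table, not asserted.
    """
    gait = gait or GaitParams(A=0.0, lifting_model="none")
    env = env or EnvironmentParams(mu_t_ratio=10.0)
    sim = sim or SimConfig(n_periods=12)
    fmap = FrictionMap(primitives=(strip,))
    env = replace(env, friction_map=fmap)
    normal = np.array([-np.sin(strip.angle), np.cos(strip.angle)])
    normal_angle = float(np.arctan2(normal[1], normal[0]))
    rows = []
    for alpha in np.atleast_1d(np.asarray(incidence_angles, dtype=float)):
        heading = normal_angle + alpha
        h = np.array([np.cos(heading), np.sin(heading)])
        com0 = np.asarray(strip.anchor, dtype=float) - approach_distance * h
        traj = simulate(gait, env, sim, SnakeState(com=com0, alpha_bar=heading))
        a_in, a_out, alpha_p, stuck_flag = _deflection(traj, fmap)
        if stuck_flag or not np.isfinite(alpha_p):
            outcome = "stuck"
        else:
            e_in = np.array([np.cos(a_in), np.sin(a_in)])
            e_out = np.array([np.cos(a_out), np.sin(a_out)])
            outcome = "reflected" if (e_in @ normal) * (e_out @ normal) < 0 else "refracted"
        rows.append(
            {"alpha": float(alpha), "alpha_p": alpha_p, "outcome": outcome, "stuck": bool(stuck_flag)}
        )
    return pd.DataFrame(rows)
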