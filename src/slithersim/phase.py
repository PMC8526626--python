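"""Gait phase-space sweeps over lifting amplitude A and phase offset Phi.

Each grid cell is an independent, deterministic simulation at fixed friction
ratio; the resulting fields of steering rate, pose angle and effective speed
organise into behavior phases separated by the zero-level contours
(separatrices) of theta_dot and gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import GaitParams
from .friction import EnvironmentParams
from .dynamics import SimConfig, simulate
from .metrics import BehaviorLabel, ClassifierConfig, compute_metrics

__all__ = ["PhaseMap", "sweep", "zero_contours", "friction_ratio_profiles"]

#: lifting strategies compared across friction ratios: no lifting, asymmetric
#: (sidewinding template), symmetric double-frequency, and curvature-coupled.
DEFAULT_STRATEGIES = {
    "no_lift": GaitParams(A=0.0, lifting_model="none"),
    "asymmetric": GaitParams(A=1.0, phi=0.25, lam=1.0),
    "symmetric": GaitParams(A=1.0, phi=0.25, lam=2.0),
    "exp_curvature": GaitParams(lifting_model="exp_curvature"),
}


@dataclass
class PhaseMap:
    """Gridded gait metrics and behavior labels over the (A, Phi) plane."""

    A_values: np.ndarray
    phi_values: np.ndarray
    mu_t_ratio: float
    theta_dot: np.ndarray  # (nA, nPhi)
    gamma: np.ndarray
    v_eff: np.ndarray
    labels: np.ndarray  # (nA, nPhi) of str
    failed: np.ndarray  # (nA, nPhi) bool, per-cell run failures
    gait_template: GaitParams = field(default_factory=GaitParams)
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    sim: SimConfig = field(default_factory=SimConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table with one row per (A, Phi) cell."""
        aa, pp = np.meshgrid(self.A_values, self.phi_values, indexing="ij")
        return pd.DataFrame(
            {
                "A": aa.ravel(),
                "Phi": pp.ravel(),
                "theta_dot": self.theta_dot.ravel(),
                "gamma": self.gamma.ravel(),
                "v_eff": self.v_eff.ravel(),
                "label": self.labels.ravel(),
                "failed": self.failed.ravel(),
            }
        )

    def separatrices(self) -> dict[str, list[np.ndarray]]:
        """Zero contours of steering rate and pose angle in (A, Phi) coordinates."""
        return {
            "theta_dot": zero_contours(self.theta_dot, self.A_values, self.phi_values),
            "gamma": zero_contours(self.gamma, self.A_values, self.phi_values),
        }


def sweep(
    A_values,
    phi_values,
    gait_template: GaitParams | None = None,
    env: EnvironmentParams | None = None,
    sim: SimConfig | None = None,
    classifier: ClassifierConfig | None = None,
    progress: bool = False,
) -> PhaseMap:
    """Simulate every (A, Phi) cell and collect metric fields and labels.

    Cells are independent (any execution order gives identical output);
    individual run failures are flagged and labeled transitional instead of
    aborting the sweep.
    """
    gait_template = gait_template or GaitParams()
    env = env or EnvironmentParams()
    sim = sim or SimConfig()
    classifier = classifier or ClassifierConfig()
    A_values = np.asarray(A_values, dtype=float)
    phi_values = np.asarray(phi_values, dtype=float)

    shape = (A_values.size, phi_values.size)
    theta = np.full(shape, np.nan)
    gamma = np.full(shape, np.nan)
    v_eff = np.full(shape, np.nan)
    labels = np.full(shape, BehaviorLabel.TRANSITION.value, dtype=object)
    failed = np.zeros(shape, dtype=bool)

    cells = [(i, j) for i in range(shape[0]) for j in range(shape[1])]
    if progress:
        from tqdm import tqdm

        cells = tqdm(cells, desc=f"sweep mu_t/mu_f={env.mu_t_ratio}")
    for i, j in cells:
        gait = gait_template.replace(A=float(A_values[i]), phi=float(phi_values[j]) % 1.0)
        try:
            traj = simulate(gait, env, sim)
            m = compute_metrics(traj, cfg=classifier)
        except Exception:
            failed[i, j] = True
            continue
        theta[i, j] = m.theta_dot
        gamma[i, j] = m.gamma
        v_eff[i, j] = m.v_eff
        labels[i, j] = m.label.value

    return PhaseMap(
        A_values=A_values,
        phi_values=phi_values,
        mu_t_ratio=env.mu_t_ratio,
        theta_dot=theta,
        gamma=gamma,
        v_eff=v_eff,
        labels=labels,
        failed=failed,
        gait_template=gait_template,
        env=env,
        sim=sim,
        classifier=classifier,
    )


def zero_contours(field_grid: np.ndarray, x_values=None, y_values=None) -> list[np.ndarray]:
    """Zero-level polylines of a gridded field (marching squares).

    Returns a list of ``(m, 2)`` vertex arrays in the coordinates of
    ``x_values`` (first grid axis) and ``y_values`` (second axis); grid
    indices are used when axes are omitted.  An all-positive or all-negative
    field yields an empty list.
    """
    from skimage import measure

    field_grid = np.asarray(field_grid, dtype=float)
    if not np.isfinite(field_grid).all():
        raise ValueError("field must be finite on the grid")
    contours = measure.find_contours(field_grid, level=0.0)
    out = []
    for c in contours:
        verts = c.copy()
        if x_values is not None:
            verts[:, 0] = np.interp(c[:, 0], np.arange(len(x_values)), np.asarray(x_values, dtype=float))
        if y_values is not None:
            verts[:, 1] = np.interp(c[:, 1], np.arange(len(y_values)), np.asarray(y_values, dtype=float))
        out.append(verts)
    return out


def friction_ratio_profiles(
    strategies: dict[str, GaitParams] | None,
    ratio_values,
    env_template: EnvironmentParams | None = None,
    sim: SimConfig | None = None,
    classifier: ClassifierConfig | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Metrics of each lifting strategy across transverse friction ratios.

    One row per (strategy, mu_t/mu_f): effective speed, steering rate, pose
    angle and behavior label, tabulating how strategies converge toward
    straight forward travel as anisotropy grows.
    """
    from dataclasses import replace

    strategies = strategies or DEFAULT_STRATEGIES
    env_template = env_template or EnvironmentParams()
    sim = sim or SimConfig()
    classifier = classifier or ClassifierConfig()

    rows = []
    items = [(name, gait, float(r)) for name, gait in strategies.items() for r in np.asarray(ratio_values, dtype=float)]
    if progress:
        from tqdm import tqdm

        items = tqdm(items, desc="friction-ratio profiles")
    for name, gait, ratio in items:
        env = replace(env_template, mu_t_ratio=ratio)
        row = {
            "strategy": name,
            "lifting_model": gait.lifting_model,
            "A": gait.A,
            "Phi": gait.phi,
            "lam": gait.lam,
            "mu_t_ratio": ratio,
        }
        try:
            traj = simulate(gait, env, sim)
            m = compute_metrics(traj, cfg=classifier)
            row.update(
                v_eff=m.v_eff,
                theta_dot=m.theta_dot,
                gamma=m.gamma,
                label=m.label.value,
                converged=m.converged,
                failed=False,
            )
        except Exception:
            row.update(
                v_eff=np.nan, theta_dot=np.nan, gamma=np.nan,
                label=BehaviorLabel.TRANSITION.value, converged=False, failed=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
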