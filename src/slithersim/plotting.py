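"""Quick-look plots: trajectories, body snapshots, phase maps."""

from __future__ import annotations

import numpy as np

from .dynamics import Trajectory
from .kinematics import reconstruct_configuration
from .phase import PhaseMap


def plot_trajectory(traj: Trajectory, ax=None, snapshots: int = 5):
    """COM path with a few body-shape snapshots overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.com[:, 0], traj.com[:, 1], "k-", lw=1, label="COM")
    grid = traj.sim.make_grid()
    for i in np.linspace(0, traj.times.size - 1, snapshots).astype(int):
        cfg = reconstruct_configuration(traj.state_at(i), traj.gait, grid)
        ax.plot(cfg.positions[:, 0], cfg.positions[:, 1], alpha=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("x (body lengths)")
    ax.set_ylabel("y (body lengths)")
    return ax


def plot_phase_map(pm: PhaseMap, field: str = "theta_dot", ax=None, separatrices: bool = True):
    """Metric field over (A, Phi) with zero-contour separatrices."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = getattr(pm, field)
    im = ax.pcolormesh(pm.phi_values, pm.A_values, grid, shading="nearest", cmap="RdBu_r")
    plt.colorbar(im, ax=ax, label=field)
    if separatrices:
        for style, polys in zip(("--", "-."), pm.separatrices().values()):
            for poly in polys:
                ax.plot(poly[:, 1], poly[:, 0], "k" + style, lw=1)
    ax.set_xlabel(r"$\Phi$ (turns)")
    ax.set_ylabel("A")
    ax.set_title(rf"$\mu_t/\mu_f$ = {pm.mu_t_ratio}")
    return ax
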