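"""Matplotlib views of trajectories, phase portraits and bifurcation scans."""

from __future__ import annotations

import numpy as np

from .bifurcation import BifurcationDiagram
from .dynamics import Trajectory
from .params import VARIABLES

__all__ = ["plot_trajectory", "plot_phase_portrait", "plot_bifurcation"]

_COLORS = {"Gp": "tab:blue", "A": "tab:orange", "Gi": "tab:red", "B": "tab:green"}


def plot_trajectory(traj: Trajectory, ax=None, variables=None):
    """Concentration time courses; biomass (if present) on a twin log axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    variables = variables or [c for c in traj.columns if c != "B"]
    for name in variables:
        ax.plot(traj.times, traj[name], label=name, color=_COLORS.get(name))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (mmol/l)")
    if traj.has_biomass:
        ax2 = ax.twinx()
        ax2.semilogy(traj.times, traj["B"], color=_COLORS["B"], label="B")
        ax2.set_ylabel("biomass (cells/l)")
    ax.legend(loc="upper right")
    return ax


def plot_phase_portrait(traj: Trajectory, ax=None):
    """3-D phase portrait of (Gp, A, Gi)."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    ax.plot(traj["Gp"], traj["A"], traj["Gi"], lw=0.8)
    ax.set_xlabel("Gp (mmol/l)")
    ax.set_ylabel("A (mmol/l)")
    ax.set_zlabel("Gi (mmol/l)")
    return ax


def plot_bifurcation(diagram: BifurcationDiagram, ax=None):
    """Steady branch of Gp with the oscillation envelope arms."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = diagram.table
    ax.plot(t["param_value"], t["branch_Gp"], "k-", label="NTSS branch")
    ax.plot(t["param_value"], t["env_min_Gp"], "b-", lw=1, label="envelope")
    ax.plot(t["param_value"], t["env_max_Gp"], "b-", lw=1)
    ax.set_xlabel(f"{diagram.parameter}")
    ax.set_ylabel("Gp (mmol/l)")
    ax.legend()
    return ax
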