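"""Minimal plotting helper (optional; requires matplotlib)."""

from __future__ import annotations

from .engine import Trajectory

_PHASE_COLORS = {"nomadic": "#cfe8ff", "colonial": "#ffe3c9", "switching": "#e8e8e8"}


def plot_trajectory(traj: Trajectory, ax=None, shade_phases: bool = True):
    """Plot n1, n2 and K against time, optionally shading the phases."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    if shade_phases:
        for ph in traj.phases:
            ax.axvspan(ph.start, ph.end,
                       color=_PHASE_COLORS.get(ph.label, "white"), alpha=0.5, lw=0)
    ax.plot(traj.times, traj.n1, label="$n_1$ (nomads)")
    ax.plot(traj.times, traj.n2, label="$n_2$ (colonists)")
    ax.plot(traj.times, traj.K, label="$K$", ls="--", color="k")
    ax.set_xlabel("scaled time")
    ax.set_ylabel("population / capacity")
    ax.legend(loc="best")
    return ax
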