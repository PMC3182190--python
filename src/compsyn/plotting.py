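"""Matplotlib helpers for trajectories and phase maps."""

from __future__ import annotations

import numpy as np

from .phasemaps import PhaseMap


def plot_phase_map(pm: PhaseMap, path=None, ax=None):
    """Heatmap of a ln timescale-ratio map; masked cells are left blank."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    data = np.ma.masked_invalid(pm.log_ratio)
    mesh = ax.pcolormesh(pm.s_grid, pm.a_grid, data, shading="nearest")
    fig.colorbar(mesh, ax=ax, label="ln timescale ratio")
    ax.set_xlabel("signal strength s")
    ax.set_ylabel("diagonal default a")
    ax.set_title(f"{pm.kind} ({pm.method})")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def plot_trajectory(t, x, path=None, ax=None, label=None):
    """Strong-fraction trajectory against time (sweeps)."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3))
    else:
        fig = ax.figure
    ax.plot(t, x, label=label)
    ax.set_xlabel("time (sweeps)")
    ax.set_ylabel("strong fraction x")
    ax.set_ylim(0, 1)
    if label:
        ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
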