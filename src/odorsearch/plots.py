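"""Minimal static figures: trajectories, track-angle histograms, PSTHs."""

from __future__ import annotations

import numpy as np

from .analysis import track_angle_histogram
from .spikes import SpikeTrainSet, psth

__all__ = ["plot_trajectories", "plot_track_angle_histogram", "plot_psth"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trajectories(trajectories, arena=None, ax=None):
    """Overlay trajectories; detections are marked with dots."""
    ax = _axes(ax)
    for traj in trajectories:
        pos = traj.positions()
        ax.plot(pos[:, 0], pos[:, 1], lw=0.8)
        hits = traj.data["n_detections"].to_numpy() > 0
        ax.plot(pos[hits, 0], pos[hits, 1], ".", ms=3, color="k")
    if arena is not None:
        ax.set_xlim(arena.x_min, arena.x_max)
        ax.set_ylim(arena.y_min, arena.y_max)
        ax.plot(*arena.source, "r*", ms=10)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m, upwind)")
    return ax


def plot_track_angle_histogram(traj, ax=None, **kwargs):
    ax = _axes(ax)
    centers, pct = track_angle_histogram(traj, **kwargs)
    ax.bar(centers, pct, width=np.diff(centers).mean() * 0.9)
    ax.set_xlabel("track angle (deg, 0 = upwind)")
    ax.set_ylabel("%")
    return ax


def plot_psth(spike_set: SpikeTrainSet, bin_s: float = 0.05, ax=None):
    ax = _axes(ax)
    edges, rates = psth(spike_set, bin_s)
    ax.step(edges, rates, where="post")
    ax.axvline(spike_set.stimulus_onset, color="r", ls="--", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("rate (spikes/s)")
    return ax
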