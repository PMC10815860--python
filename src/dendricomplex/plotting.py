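"""Small matplotlib helpers for profiles and sectoral half-disc maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fields import RadialProfile, SectoralMap
from .shape import TimeSeries

__all__ = ["plot_timeseries", "plot_radial_profile", "plot_sectoral_map"]


def plot_timeseries(ts: TimeSeries, path: str | Path, **kwargs) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(ts.times / 1000.0, ts.values, **kwargs)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel(f"{ts.label} ({ts.units})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_radial_profile(profile: RadialProfile, path: str | Path, **kwargs) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.centers, profile.values, drawstyle="steps-mid", **kwargs)
    ax.set_xlabel("r (nm)")
    ax.set_ylabel(f"{profile.quantity} ({profile.units})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_sectoral_map(smap: SectoralMap, path: str | Path, cmap: str = "viridis") -> Path:
    """Two polar half-discs: upper half on the left, lower half on the right."""
    fig, axes = plt.subplots(
        1, 2, figsize=(8, 4), subplot_kw={"projection": "polar"}
    )
    vmax = max(smap.upper.max(), smap.lower.max()) or 1.0
    for ax, arr, title in ((axes[0], smap.upper, "upper"), (axes[1], smap.lower, "lower")):
        theta, r = np.meshgrid(smap.theta_edges, smap.r_edges)
        pcm = ax.pcolormesh(theta, r, arr, cmap=cmap, vmin=0.0, vmax=vmax)
        ax.set_thetamin(0)
        ax.set_thetamax(180)
        ax.set_title(f"{title} half")
    fig.colorbar(pcm, ax=axes, label="mass (g/mol)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
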