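"""Shape descriptors and complexation time-series analysis.

Implements the standard host-guest complexation observables:

* ``com_distance`` — d(t), the minimum-image distance between the
  mass-weighted centres of mass of two selections,
* ``radius_of_gyration`` — Rg = sqrt(sum m_i |r_i - r_com|^2 / sum m_i),
* ``gyration_summary`` — eigenvalues of the mass-weighted gyration tensor
  and the asphericity alpha = 1 - 3 I2 / I1^2 built from its first two
  elementary symmetric invariants (I1 = l1+l2+l3, I2 = l1 l2 + l2 l3 +
  l1 l3); alpha = 0 for a sphere and 1 for a rod,
* ``rg_distribution`` — the normalised histogram P(Rg) over a frame window,
* ``detect_complexation`` — first time a smoothed d(t) stays below a
  threshold for a sustained hold, the "abrupt step-like drop" signature of
  stable complex formation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgsim import Trajectory

__all__ = [
    "TimeSeries",
    "GyrationSummary",
    "Histogram",
    "com_distance",
    "radius_of_gyration",
    "gyration_summary",
    "rg_distribution",
    "rg_series",
    "detect_complexation",
    "unwrap_cluster",
    "NOT_FORMED",
]

NOT_FORMED = "not formed"


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class GyrationSummary:
    """Rg (nm), sorted gyration-tensor eigenvalues (nm^2), invariants, alpha."""

    Rg: float
    eigenvalues: tuple  # (l1 >= l2 >= l3), nm^2
    I1: float  # nm^2
    I2: float  # nm^4
    alpha: float
    degenerate: bool = False


def _resolve_selection(traj_or_frame, selection) -> np.ndarray:
    if selection is None:
        n = traj_or_frame.positions.shape[-2]
        return np.ones(n, dtype=bool)
    if isinstance(selection, str):
        return traj_or_frame.select(selection)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        return sel
    n = traj_or_frame.positions.shape[-2]
    mask = np.zeros(n, dtype=bool)
    mask[sel] = True
    return mask


def _check_selection(mask: np.ndarray, masses: np.ndarray) -> None:
    if not mask.any():
        raise ValueError("empty selection")
    if masses[mask].sum() <= 0:
        raise ValueError("selection has zero total mass")


def com_distance(traj: Trajectory, sel_a, sel_b, label: str = "d") -> TimeSeries:
    """Minimum-image COM-COM distance per frame, nm."""
    a = _resolve_selection(traj, sel_a)
    b = _resolve_selection(traj, sel_b)
    _check_selection(a, traj.masses)
    _check_selection(b, traj.masses)
    ma = traj.masses[a]
    mb = traj.masses[b]
    com_a = (ma[None, :, None] * traj.positions[:, a]).sum(1) / ma.sum()
    com_b = (mb[None, :, None] * traj.positions[:, b]).sum(1) / mb.sum()
    delta = com_b - com_a
    delta -= traj.box * np.round(delta / traj.box)
    return TimeSeries(traj.times, np.linalg.norm(delta, axis=1), label=label, units="nm")


def radius_of_gyration(positions: np.ndarray, masses: np.ndarray, mask=None) -> float:
    """Mass-weighted radius of gyration of one frame (nm).

    Coordinates must be unwrapped (or the cluster contiguous in the box);
    use :func:`unwrap_cluster` first for wrapped periodic frames.
    """
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if mask is not None:
        positions = positions[mask]
        masses = masses[mask]
    if len(positions) == 0:
        raise ValueError("empty selection")
    if masses.sum() <= 0:
        raise ValueError("selection has zero total mass")
    com = (masses[:, None] * positions).sum(0) / masses.sum()
    return float(np.sqrt((masses * ((positions - com) ** 2).sum(1)).sum() / masses.sum()))


def gyration_summary(positions: np.ndarray, masses: np.ndarray, mask=None) -> GyrationSummary:
    """Eigen-decompose the mass-weighted gyration tensor of one frame."""
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if mask is not None:
        positions = positions[mask]
        masses = masses[mask]
    if len(positions) < 2:
        raise ValueError("gyration summary needs at least 2 beads")
    com = (masses[:, None] * positions).sum(0) / masses.sum()
    dx = positions - com
    tensor = (masses[:, None, None] * dx[:, :, None] * dx[:, None, :]).sum(0) / masses.sum()
    lam = np.linalg.eigvalsh(tensor)[::-1]  # descending
    lam = np.clip(lam, 0.0, None)
    # flush eigenvalues at numerical noise level so degenerate (collinear,
    # planar) configurations give exact invariants
    if lam[0] > 0.0:
        lam[lam < 1e-12 * lam[0]] = 0.0
    i1 = float(lam.sum())
    i2 = float(lam[0] * lam[1] + lam[1] * lam[2] + lam[0] * lam[2])
    if i1 == 0.0:
        return GyrationSummary(0.0, tuple(lam), 0.0, 0.0, float("nan"), degenerate=True)
    alpha = 1.0 - 3.0 * i2 / i1**2
    return GyrationSummary(float(np.sqrt(i1)), tuple(float(x) for x in lam), i1, i2, float(alpha))


def rg_series(traj: Trajectory, selection=None, label: str = "Rg") -> TimeSeries:
    """Per-frame radius of gyration of a selection."""
    mask = _resolve_selection(traj, selection)
    _check_selection(mask, traj.masses)
    vals = [radius_of_gyration(traj.positions[i], traj.masses, mask) for i in range(traj.n_frames)]
    return TimeSeries(traj.times, np.asarray(vals), label=label, units="nm")


@dataclass
class Histogram:
    edges: np.ndarray
    probabilities: np.ndarray
    normalized: bool = True

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    def std(self) -> float:
        w = self.probabilities * np.diff(self.edges)
        mu = (self.centers * w).sum() / w.sum()
        return float(np.sqrt(((self.centers - mu) ** 2 * w).sum() / w.sum()))


def rg_distribution(
    traj: Trajectory,
    selection=None,
    bin_width: float = 0.02,
    window: tuple[int, int] | None = None,
) -> Histogram:
    """Normalised P(Rg) histogram over a frame window (default: all frames)."""
    series = rg_series(traj, selection)
    lo, hi = (0, traj.n_frames) if window is None else window
    vals = series.values[lo:hi]
    if len(vals) == 0:
        raise ValueError("empty frame window")
    vmin = np.floor(vals.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((vals.max() - vmin) / bin_width + 1e-12)))
    edges = vmin + bin_width * np.arange(nbins + 1)
    prob, edges = np.histogram(vals, bins=edges, density=True)
    return Histogram(edges, prob, normalized=True)


def running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with truncated endpoints."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def detect_complexation(
    d: TimeSeries,
    threshold: float,
    hold: float | None = None,
    smooth_window: int = 21,
):
    """First time the smoothed d(t) stays below ``threshold`` for ``hold`` ps.

    Returns the formation time (ps) or the string ``"not formed"``. ``hold``
    defaults to 10% of the series duration.
    """
    duration = d.times[-1] - d.times[0]
    if hold is None:
        hold = 0.1 * duration
    if hold >= duration:
        raise ValueError("hold must be shorter than the series duration")
    smoothed = running_mean(d.values, smooth_window)
    below = smoothed < threshold
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag:
            if start is not None and d.times[i - 1] - d.times[start] >= hold:
                return float(d.times[start])
            start = None
    if start is not None and d.times[-1] - d.times[start] >= hold:
        return float(d.times[start])
    return NOT_FORMED


def unwrap_cluster(
    positions: np.ndarray,
    box: np.ndarray,
    bonds: list | None = None,
    seed_index: int = 0,
) -> np.ndarray:
    """Unwrap a wrapped periodic frame into a contiguous cluster.

    Grows from ``seed_index`` across bonds if given, otherwise across a
    nearest-neighbour chain in index order, moving each bead to the minimum
    image relative to its already-unwrapped anchor.
    """
    positions = np.asarray(positions, dtype=float).copy()
    box = np.asarray(box, dtype=float)
    n = len(positions)
    if bonds:
        adj = {i: set() for i in range(n)}
        for b in bonds:
            adj[b[0]].add(b[1])
            adj[b[1]].add(b[0])
        seen = {seed_index}
        stack = [seed_index]
        while stack:
            u = stack.pop()
            for v in sorted(adj[u]):
                if v not in seen:
                    seen.add(v)
                    delta = positions[v] - positions[u]
                    positions[v] -= box * np.round(delta / box)
                    stack.append(v)
    else:
        for i in range(1, n):
            delta = positions[i] - positions[i - 1]
            positions[i] -= box * np.round(delta / box)
    return positions
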