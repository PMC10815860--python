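"""Radial and sectoral mass fields around a chosen centre of mass.

``radial_density`` computes rho(r) = m(r)/V(r): the frame-averaged mass of
beads in a thin spherical shell at distance r from the centre selection's
COM, divided by the shell volume, converted to g/cm^3. ``sectoral_mass_map``
resolves the same mass radially *and* in the polar angle theta measured from
the host-to-guest axis, split into two azimuthal halves — the 2D sectoral
encapsulation picture that shows where host material surrounds the guest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cgsim import Trajectory
from .shape import _check_selection, _resolve_selection
from .units import N_AVOGADRO

__all__ = ["RadialProfile", "SectoralMap", "radial_density", "sectoral_mass_map", "radial_mass"]

#: g/mol per nm^3  ->  g/cm^3
DENSITY_CONV = 1.0 / N_AVOGADRO * 1e21


@dataclass
class RadialProfile:
    """Binned radial function with explicit shell geometry."""

    edges: np.ndarray  # nm, strictly increasing from 0
    values: np.ndarray  # one per bin
    quantity: str  # "density" | "mass" | "charge" | "cumulative_charge" | "potential"
    units: str
    center: str = "com"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.edges[0] < 0 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must increase strictly from >= 0")
        if len(self.values) != len(self.edges) - 1:
            raise ValueError("need one value per bin")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite profile values")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    @property
    def shell_volumes(self) -> np.ndarray:
        """4 pi/3 (r_{k+1}^3 - r_k^3), nm^3."""
        return 4.0 * np.pi / 3.0 * np.diff(self.edges**3)


def _radial_distances(traj, sel_mask, center_mask, frames):
    """Per-frame bead distances to the centre selection's COM."""
    mc = traj.masses[center_mask]
    for i in frames:
        pos = traj.positions[i]
        com = (mc[:, None] * pos[center_mask]).sum(0) / mc.sum()
        yield i, np.linalg.norm(pos[sel_mask] - com, axis=1), pos, com


def radial_mass(
    traj: Trajectory,
    selection,
    center_selection=None,
    bin_width: float = 0.05,
    window: tuple[int, int] | None = None,
    r_max: float | None = None,
) -> RadialProfile:
    """Frame-averaged mass per spherical shell, g/mol per shell."""
    sel = _resolve_selection(traj, selection)
    cen = _resolve_selection(traj, center_selection)
    _check_selection(sel, traj.masses)
    _check_selection(cen, traj.masses)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = (0, traj.n_frames) if window is None else window
    frames = range(lo, hi)
    if len(frames) == 0:
        raise ValueError("empty frame window")

    all_r = []
    for _, r, _, _ in _radial_distances(traj, sel, cen, frames):
        all_r.append(r)
    rmax = max(a.max() for a in all_r) if r_max is None else r_max
    nbins = max(1, int(np.ceil(rmax / bin_width + 1e-12)))
    edges = bin_width * np.arange(nbins + 1)
    masses = traj.masses[sel]
    acc = np.zeros(nbins)
    for r in all_r:
        h, _ = np.histogram(r, bins=edges, weights=masses)
        acc += h
    acc /= len(all_r)
    return RadialProfile(edges, acc, "mass", "g/mol", metadata={"n_frames": len(all_r)})


def radial_density(
    traj: Trajectory,
    selection,
    center_selection=None,
    bin_width: float = 0.05,
    window: tuple[int, int] | None = None,
    r_max: float | None = None,
) -> RadialProfile:
    """rho(r) in g/cm^3: frame-averaged shell mass over shell volume."""
    m = radial_mass(traj, selection, center_selection, bin_width, window, r_max)
    rho = m.values / m.shell_volumes * DENSITY_CONV
    return RadialProfile(m.edges, rho, "density", "g/cm^3", metadata=m.metadata)


@dataclass
class SectoralMap:
    """(radius x polar angle) mass maps for the upper and lower azimuthal halves.

    theta is measured from the host-COM -> guest-COM axis; the azimuthal
    split uses the laboratory +z axis component orthogonal to that axis as
    the phi = 0 reference (falling back to +x when the axis is parallel to
    z). Cells hold frame-averaged mass in g/mol.
    """

    r_edges: np.ndarray
    theta_edges: np.ndarray  # radians over [0, pi]
    upper: np.ndarray  # (n_r, n_theta)
    lower: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        self.theta_edges = np.asarray(self.theta_edges, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        if np.any(self.upper < 0) or np.any(self.lower < 0):
            raise ValueError("sectoral cells must be non-negative")

    def total_mass(self) -> float:
        return float(self.upper.sum() + self.lower.sum())

    def radial_marginal(self) -> np.ndarray:
        """Sum over theta and both halves: the radial mass histogram m(r)."""
        return self.upper.sum(axis=1) + self.lower.sum(axis=1)


def sectoral_mass_map(
    traj: Trajectory,
    selection,
    axis_from,
    axis_to,
    n_theta: int = 18,
    bin_width: float = 0.05,
    window: tuple[int, int] | None = None,
    r_max: float | None = None,
) -> SectoralMap:
    """2D sectoral radial mass distribution, frame-averaged.

    Frames where the two axis-group COMs coincide are skipped with a warning
    recorded in the metadata.
    """
    sel = _resolve_selection(traj, selection)
    src = _resolve_selection(traj, axis_from)
    dst = _resolve_selection(traj, axis_to)
    for mask in (sel, src, dst):
        _check_selection(mask, traj.masses)
    lo, hi = (0, traj.n_frames) if window is None else window
    frames = list(range(lo, hi))
    if not frames:
        raise ValueError("empty frame window")

    masses = traj.masses[sel]
    m_src = traj.masses[src]
    m_dst = traj.masses[dst]

    # first pass: max radius
    dists = []
    axes = []
    skipped = 0
    used_frames = []
    for i in frames:
        pos = traj.positions[i]
        com_s = (m_src[:, None] * pos[src]).sum(0) / m_src.sum()
        com_d = (m_dst[:, None] * pos[dst]).sum(0) / m_dst.sum()
        u = com_d - com_s
        norm = np.linalg.norm(u)
        if norm < 1e-12:
            skipped += 1
            continue
        u /= norm
        rel = pos[sel] - com_s
        dists.append(np.linalg.norm(rel, axis=1))
        axes.append((u, rel))
        used_frames.append(i)
    if not used_frames:
        raise ValueError("all frames skipped: coincident axis COMs")

    rmax = max(d.max() for d in dists) if r_max is None else r_max
    n_r = max(1, int(np.ceil(rmax / bin_width + 1e-12)))
    r_edges = bin_width * np.arange(n_r + 1)
    theta_edges = np.linspace(0.0, np.pi, n_theta + 1)

    upper = np.zeros((n_r, n_theta))
    lower = np.zeros((n_r, n_theta))
    zlab = np.array([0.0, 0.0, 1.0])
    xlab = np.array([1.0, 0.0, 0.0])
    for (u, rel), r in zip(axes, dists):
        rsafe = np.maximum(r, 1e-12)
        ct = np.clip(rel @ u / rsafe, -1.0, 1.0)
        theta = np.arccos(ct)
        # azimuthal reference: lab +z orthogonalised against u (fallback +x)
        ref = zlab - (zlab @ u) * u
        if np.linalg.norm(ref) < 1e-8:
            ref = xlab - (xlab @ u) * u
        ref /= np.linalg.norm(ref)
        ref2 = np.cross(u, ref)
        perp = rel - np.outer(rel @ u, u)
        phi = np.arctan2(perp @ ref2, perp @ ref) % (2.0 * np.pi)
        is_upper = phi < np.pi
        for half, mask in ((upper, is_upper), (lower, ~is_upper)):
            h, _, _ = np.histogram2d(
                r[mask], theta[mask], bins=[r_edges, theta_edges], weights=masses[mask]
            )
            half += h
    upper /= len(used_frames)
    lower /= len(used_frames)
    return SectoralMap(
        r_edges,
        theta_edges,
        upper,
        lower,
        metadata={"n_frames": len(used_frames), "skipped_frames": skipped},
    )
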