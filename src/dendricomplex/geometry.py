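"""Bead-level 3D geometry: fullerene cages and dendrimer embeddings.

The coarse-grained resolution is one bead per residue for dendrimers and one
bead per carbon for fullerenes. Units are nm / g/mol / e throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .topology import DendrimerTopology, fullerene_composition
from .units import MASS_CARBON

__all__ = [
    "BeadConformation",
    "make_fullerene_cage",
    "embed_dendrimer",
    "place_guest",
    "GROUP_DENDRIMER",
    "GROUP_FULLERENE",
    "GROUP_COUNTERION",
    "GROUP_WATER",
]

GROUP_DENDRIMER = "dendrimer"
GROUP_FULLERENE = "fullerene"
GROUP_COUNTERION = "counterion"
GROUP_WATER = "water"

#: C60 van der Waals cage diameter, nm (carbon-centre diameter ~0.71 nm)
C60_DIAMETER = 0.71


@dataclass
class BeadConformation:
    """Positions (n x 3, nm) with per-bead mass, charge and group label."""

    positions: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    groups: np.ndarray  # array of strings
    box: np.ndarray = field(default_factory=lambda: np.array([10.0, 10.0, 10.0]))
    bonds: list = field(default_factory=list)  # (i, j, r0, k) or (i, j)
    names: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if not (len(self.masses) == len(self.charges) == len(self.groups) == n):
            raise ValueError("per-bead arrays must share one length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def select(self, group: str) -> np.ndarray:
        """Boolean mask of beads whose group label equals ``group``."""
        return self.groups == group

    def com(self, mask: np.ndarray | None = None) -> np.ndarray:
        m = self.masses if mask is None else self.masses[mask]
        x = self.positions if mask is None else self.positions[mask]
        if m.sum() <= 0:
            raise ValueError("selection has zero total mass")
        return (m[:, None] * x).sum(axis=0) / m.sum()

    def copy(self) -> "BeadConformation":
        return replace(
            self,
            positions=self.positions.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            groups=self.groups.copy(),
            box=self.box.copy(),
            bonds=list(self.bonds),
            names=None if self.names is None else self.names.copy(),
        )


def _truncated_icosahedron() -> np.ndarray:
    """Unit-edge-2 truncated icosahedron: 60 vertices, vertex-transitive."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    seeds = [
        (0.0, 1.0, 3.0 * phi),
        (1.0, 2.0 + phi, 2.0 * phi),
        (phi, 2.0, 2.0 * phi + 1.0),
    ]
    verts = set()
    for seed in seeds:
        for cyc in range(3):
            base = seed[cyc:] + seed[:cyc]
            for sx in (-1.0, 1.0):
                for sy in (-1.0, 1.0):
                    for sz in (-1.0, 1.0):
                        verts.add(
                            (round(base[0] * sx, 12), round(base[1] * sy, 12), round(base[2] * sz, 12))
                        )
    arr = np.array(sorted(verts))
    assert arr.shape == (60, 3)
    return arr


def make_fullerene_cage(n_carbons: int, box: float | np.ndarray = 10.0) -> BeadConformation:
    """Rigid carbon cage centred at the origin.

    C60 is the truncated icosahedron scaled to a 0.71 nm carbon-centre
    diameter. C70 adds an equatorial belt of 10 carbons between the two C60
    hemispheres (idealised D5h construction with uniform edge lengths).
    """
    fullerene_composition(n_carbons)  # validates the size
    ti = _truncated_icosahedron()
    # orient a five-fold axis (through a pentagon centre) along z so the D5h
    # belt construction below splits the cage into 30/30 hemispheres
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    a = np.array([0.0, 1.0, phi])
    a /= np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    s, c = np.linalg.norm(v), float(a @ z)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    ti = ti @ rot.T

    radius = np.linalg.norm(ti, axis=1).mean()
    scale = (C60_DIAMETER / 2.0) / radius
    coords = ti * scale

    if n_carbons == 70:
        # split hemispheres along z, push apart by one bond length, insert a
        # 10-ring at the equator at the cage radius
        bond = scale * 2.0  # edge length of the scaled truncated icosahedron
        upper = coords[coords[:, 2] > 0] + [0, 0, bond / 2.0]
        lower = coords[coords[:, 2] < 0] - [0, 0, bond / 2.0]
        ring_r = C60_DIAMETER / 2.0
        ang = 2.0 * np.pi * np.arange(10) / 10.0 + np.pi / 10.0
        belt = np.column_stack([ring_r * np.cos(ang), ring_r * np.sin(ang), np.zeros(10)])
        coords = np.vstack([upper, belt, lower])

    coords = coords - coords.mean(axis=0)
    n = len(coords)
    box = np.broadcast_to(np.atleast_1d(np.asarray(box, float)), (3,)).copy()
    return BeadConformation(
        positions=coords + box / 2.0,
        masses=np.full(n, MASS_CARBON),
        charges=np.zeros(n),
        groups=np.array([GROUP_FULLERENE] * n, dtype=object),
        box=box,
        names=np.array(["C"] * n, dtype=object),
    )


def embed_dendrimer(
    topology: DendrimerTopology,
    bond_length: float = 0.5,
    seed: int = 0,
    box: float | np.ndarray = 10.0,
    min_separation_factor: float = 0.8,
    max_retries: int = 400,
) -> BeadConformation:
    """Self-avoiding branching-walk embedding of a residue tree.

    Beads are placed breadth-first from the core; each child is dropped at
    ``bond_length`` from its parent in a random direction, rejecting
    placements closer than ``min_separation_factor * bond_length`` to any
    non-bonded bead already placed. Deterministic for a fixed seed.
    """
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    topology.validate()
    rng = np.random.default_rng(seed)
    box = np.broadcast_to(np.atleast_1d(np.asarray(box, float)), (3,)).copy()

    ids = sorted(topology.residues)
    index = {rid: k for k, rid in enumerate(ids)}
    n = len(ids)
    children: dict[int, list[int]] = {rid: [] for rid in ids}
    parent: dict[int, int] = {}
    adj: dict[int, set[int]] = {rid: set() for rid in ids}
    for a, b in topology.edges:
        adj[a].add(b)
        adj[b].add(a)
    # orient edges away from the core
    order = [topology.core_id]
    seen = {topology.core_id}
    qi = 0
    while qi < len(order):
        u = order[qi]
        qi += 1
        for v in sorted(adj[u]):
            if v not in seen:
                seen.add(v)
                parent[v] = u
                children[u].append(v)
                order.append(v)

    min_sep = min_separation_factor * bond_length
    for attempt in range(8):
        pos = np.zeros((n, 3))
        pos[index[topology.core_id]] = box / 2.0
        ok = True
        for rid in order[1:]:
            p = pos[index[parent[rid]]]
            placed = [index[r] for r in order[: order.index(rid)]]
            others = [k for k in placed if k != index[parent[rid]]]
            success = False
            for _ in range(max_retries):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = p + bond_length * v
                if others and np.min(np.linalg.norm(pos[others] - cand, axis=1)) < min_sep:
                    continue
                pos[index[rid]] = cand
                success = True
                break
            if not success:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            f"self-avoiding embedding failed after {max_retries} retries x 8 restarts"
        )

    specs = [topology.residues[rid] for rid in ids]
    bonds = [
        (index[a], index[b], bond_length, None) for a, b in topology.edges
    ]
    return BeadConformation(
        positions=pos,
        masses=np.array([s.mass for s in specs]),
        charges=np.array([float(s.charge) for s in specs]),
        groups=np.array([GROUP_DENDRIMER] * n, dtype=object),
        box=box,
        bonds=bonds,
        names=np.array([s.name for s in specs], dtype=object),
    )


def bounding_radius(conf: BeadConformation, mask: np.ndarray | None = None) -> float:
    """Largest bead distance from the selection's centre of mass."""
    x = conf.positions if mask is None else conf.positions[mask]
    return float(np.linalg.norm(x - conf.com(mask), axis=1).max())


def place_guest(
    host: BeadConformation,
    guest: BeadConformation,
    offset: float = 4.5,
    axis: str = "x",
) -> BeadConformation:
    """Combine host and guest with their COMs separated by ``offset`` nm.

    The guest is translated rigidly along the chosen laboratory axis so the
    guest sits outside the host's bounding sphere, mirroring an initial
    configuration with the cage placed well outside the dendrimer.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    try:
        k = {"x": 0, "y": 1, "z": 2}[axis]
    except KeyError:
        raise ValueError(f"axis must be x, y or z, got {axis!r}") from None
    r_host = bounding_radius(host)
    r_guest = bounding_radius(guest)
    if offset < r_host + r_guest:
        raise ValueError(
            f"offset {offset} nm places the guest inside the host "
            f"(bounding radii sum to {r_host + r_guest:.3f} nm)"
        )
    shift = np.zeros(3)
    shift[k] = offset
    target = host.com() + shift
    gpos = guest.positions + (target - guest.com())

    nh = host.n_beads
    bonds = list(host.bonds)
    for b in guest.bonds:
        i, j, r0, kk = b if len(b) == 4 else (b[0], b[1], None, None)
        bonds.append((i + nh, j + nh, r0, kk))
    names = None
    if host.names is not None and guest.names is not None:
        names = np.concatenate([host.names, guest.names])
    return BeadConformation(
        positions=np.vstack([host.positions, gpos]),
        masses=np.concatenate([host.masses, guest.masses]),
        charges=np.concatenate([host.charges, guest.charges]),
        groups=np.concatenate([host.groups, guest.groups]),
        box=host.box.copy(),
        bonds=bonds,
        names=names,
    )
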