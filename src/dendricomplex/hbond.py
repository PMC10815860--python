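"""Geometric hydrogen-bond counting on all-atom frames.

A hydrogen bond is counted for a (donor D with covalently bonded H,
acceptor A) pair when the D-A minimum-image distance is below the distance
cutoff and the bond is sufficiently linear. Two angle conventions are
exposed:

* ``"HDA"`` (default): the angle H-D-A at the donor must be <= the angle
  cutoff (the 0.35 nm / 30 degree criterion that trajectory-analysis
  toolchains use by default),
* ``"DHA"``: the angle D-H...A at the hydrogen must be >= 180 degrees
  minus the angle cutoff.

Donor-acceptor pairs belonging to the same molecule are never counted, so
overlapping donor/acceptor selections do not produce intramolecular
self-pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AtomFrame", "HBondCriteria", "count_hbonds"]


@dataclass
class AtomFrame:
    """All-atom snapshot: positions (nm), element symbols, covalent bonds."""

    positions: np.ndarray
    elements: np.ndarray
    bonds: list  # (i, j) covalent pairs
    molecule_ids: np.ndarray
    box: np.ndarray = field(default_factory=lambda: np.array([1e6, 1e6, 1e6]))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if not (len(self.elements) == len(self.molecule_ids) == n):
            raise ValueError("per-atom arrays must share one length")

    def bonded_hydrogens(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i and self.elements[b] == "H":
                out.append(b)
            elif b == i and self.elements[a] == "H":
                out.append(a)
        return out


@dataclass(frozen=True)
class HBondCriteria:
    """Distance (nm) and angle (degrees) cutoffs plus the angle convention."""

    distance_cutoff: float = 0.35
    angle_cutoff: float = 30.0
    angle_convention: str = "HDA"

    def __post_init__(self):
        if not 0.0 < self.distance_cutoff < 1.0:
            raise ValueError("distance cutoff must lie in (0, 1) nm")
        if not 0.0 < self.angle_cutoff < 90.0:
            raise ValueError("angle cutoff must lie in (0, 90) degrees")
        if self.angle_convention not in ("HDA", "DHA"):
            raise ValueError("angle convention must be 'HDA' or 'DHA'")


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _angle(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def count_hbonds(
    frame: AtomFrame,
    donors,
    acceptors,
    criteria: HBondCriteria | None = None,
) -> int:
    """Count hydrogen bonds between donor and acceptor heavy atoms.

    ``donors``/``acceptors`` are index arrays or boolean masks over the
    frame's atoms; donors must each carry at least one covalently bonded
    hydrogen (a donor without hydrogens raises — no inference is done).
    Each (D-H, A) combination satisfying the criteria counts once.
    """
    if criteria is None:
        criteria = HBondCriteria()
    donors = _as_indices(donors, len(frame.positions))
    acceptors = _as_indices(acceptors, len(frame.positions))
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("empty donor or acceptor selection")

    hydrogens = {}
    for d in donors:
        hs = frame.bonded_hydrogens(int(d))
        if not hs:
            raise ValueError(
                f"donor atom {d} ({frame.elements[d]}) has no bonded hydrogen"
            )
        hydrogens[int(d)] = hs

    count = 0
    pos = frame.positions
    box = frame.box
    for d in donors:
        d = int(d)
        for a in acceptors:
            a = int(a)
            if a == d or frame.molecule_ids[a] == frame.molecule_ids[d]:
                continue
            da = _min_image(pos[a] - pos[d], box)
            if np.linalg.norm(da) > criteria.distance_cutoff:
                continue
            for h in hydrogens[d]:
                dh = _min_image(pos[h] - pos[d], box)
                if criteria.angle_convention == "HDA":
                    ok = _angle(dh, da) <= criteria.angle_cutoff
                else:  # DHA: angle at the hydrogen
                    ha = _min_image(pos[a] - pos[h], box)
                    ok = _angle(-dh, ha) >= 180.0 - criteria.angle_cutoff
                if ok:
                    count += 1
    return count


def _as_indices(sel, n: int) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if len(sel) != n:
            raise ValueError("boolean selection length mismatch")
        return np.where(sel)[0]
    return sel.astype(int)
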