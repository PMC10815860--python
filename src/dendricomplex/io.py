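"""File I/O: XYZ trajectories with JSON sidecars, PDB/GRO via MDAnalysis, CSV.

Trajectories are stored as multi-frame XYZ (portable, diffable) plus a JSON
sidecar carrying what XYZ cannot: per-bead masses, charges, group labels,
the box, and run metadata. PDB and GRO coordinate files (and, where the
reader supports them, XTC/DCD) are handled through MDAnalysis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cgsim import Trajectory
from .fields import RadialProfile, SectoralMap
from .geometry import BeadConformation
from .shape import Histogram, TimeSeries

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_coordinates",
    "timeseries_to_csv",
    "profile_to_csv",
    "sectoral_map_to_csv",
]

_GROUP_SYMBOL = {"dendrimer": "N", "fullerene": "C", "counterion": "Cl", "water": "O"}
_SYMBOL_GROUP = {v: k for k, v in _GROUP_SYMBOL.items()}


def write_xyz(traj: Trajectory, path: str | Path, sidecar: bool = True) -> Path:
    """Write a multi-frame XYZ file (Angstrom, the format's convention)."""
    path = Path(path)
    symbols = [_GROUP_SYMBOL.get(g, "X") for g in traj.groups]
    with path.open("w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(f"t= {traj.times[k]:.6f} ps\n")
            for sym, xyz in zip(symbols, traj.positions[k] * 10.0):
                fh.write(f"{sym} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
    if sidecar:
        meta = {
            "masses": traj.masses.tolist(),
            "charges": traj.charges.tolist(),
            "groups": list(traj.groups),
            "box": traj.box.tolist(),
            "times": traj.times.tolist(),
            "unwrapped": traj.unwrapped,
            "metadata": traj.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_xyz(path: str | Path, sidecar: str | Path | None = None) -> Trajectory:
    """Read a multi-frame XYZ written by :func:`write_xyz`."""
    path = Path(path)
    frames = []
    times = []
    symbols = None
    with path.open() as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            try:
                times.append(float(comment.split()[1]))
            except (IndexError, ValueError):
                times.append(float(len(times)))
            syms, coords = [], []
            for _ in range(n):
                parts = fh.readline().split()
                syms.append(parts[0])
                coords.append([float(x) for x in parts[1:4]])
            frames.append(np.asarray(coords) / 10.0)
            symbols = syms
    positions = np.asarray(frames)

    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return Trajectory(
            positions=positions,
            times=np.asarray(meta["times"]),
            masses=np.asarray(meta["masses"]),
            charges=np.asarray(meta["charges"]),
            groups=np.asarray(meta["groups"], dtype=object),
            box=np.asarray(meta["box"]),
            metadata=meta.get("metadata", {}),
            unwrapped=meta.get("unwrapped", True),
        )
    n = positions.shape[1]
    groups = np.array([_SYMBOL_GROUP.get(s, "dendrimer") for s in symbols], dtype=object)
    return Trajectory(
        positions=positions,
        times=np.asarray(times),
        masses=np.ones(n),
        charges=np.zeros(n),
        groups=groups,
        box=np.full(3, 1e6),
    )


def write_pdb(conf: BeadConformation, path: str | Path) -> Path:
    """Write one conformation as PDB (via MDAnalysis; nm -> Angstrom)."""
    import MDAnalysis as mda

    path = Path(path)
    n = conf.n_beads
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    names = conf.names if conf.names is not None else np.array(
        [_GROUP_SYMBOL.get(g, "X") for g in conf.groups], dtype=object
    )
    u.add_TopologyAttr("name", [str(x)[:4] for x in names])
    u.add_TopologyAttr("resname", [str(g)[:4].upper() for g in conf.groups])
    u.add_TopologyAttr("resid", np.arange(1, n + 1))
    u.add_TopologyAttr("masses", conf.masses)
    u.add_TopologyAttr("charges", conf.charges)
    u.atoms.positions = conf.positions * 10.0
    u.dimensions = [conf.box[0] * 10, conf.box[1] * 10, conf.box[2] * 10, 90, 90, 90]
    u.atoms.write(str(path))
    return path


_RESNAME_GROUP = {
    # 4-char truncations of this package's own group labels
    "DEND": "dendrimer",
    "FULL": "fullerene",
    "COUN": "counterion",
    "WATE": "water",
    "FUL": "fullerene",
    "C60": "fullerene",
    "C70": "fullerene",
    "CL": "counterion",
    "ION": "counterion",
    "SOL": "water",
    "HOH": "water",
    "WAT": "water",
    "TIP3": "water",
}


def read_coordinates(path: str | Path, trajectory: str | Path | None = None) -> Trajectory:
    """Read PDB/GRO/XYZ coordinates (optionally with XTC/DCD) via MDAnalysis.

    Group labels are inferred from residue names (unrecognised residues are
    labelled ``dendrimer``); masses and charges fall back to 1 / 0 where
    the file carries none.
    """
    import MDAnalysis as mda

    args = (str(path),) if trajectory is None else (str(path), str(trajectory))
    u = mda.Universe(*args)
    n = len(u.atoms)
    try:
        masses = u.atoms.masses.copy()
        if not np.all(masses > 0):
            raise ValueError
    except Exception:
        masses = np.ones(n)
    try:
        charges = u.atoms.charges.copy()
    except Exception:
        charges = np.zeros(n)
    try:
        resnames = [str(r).upper() for r in u.atoms.resnames]
    except Exception:
        resnames = ["UNK"] * n
    groups = np.array(
        [_RESNAME_GROUP.get(r, "dendrimer") for r in resnames], dtype=object
    )
    positions = []
    times = []
    for ts in u.trajectory:
        positions.append(u.atoms.positions.copy() / 10.0)
        times.append(float(ts.time) if np.isfinite(ts.time) else float(len(times)))
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(len(times), dtype=float)
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    else:
        box = np.full(3, 1e6)
    return Trajectory(
        positions=np.asarray(positions),
        times=times,
        masses=masses,
        charges=charges,
        groups=groups,
        box=box,
        unwrapped=False,
    )


def timeseries_to_csv(ts: TimeSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_ps": ts.times, ts.label or "value": ts.values})
    with path.open("w") as fh:
        fh.write(f"# label={ts.label} units={ts.units}\n")
        df.to_csv(fh, index=False)
    return path


def profile_to_csv(profile: RadialProfile, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "r_lo_nm": profile.edges[:-1],
            "r_hi_nm": profile.edges[1:],
            profile.quantity: profile.values,
        }
    )
    with path.open("w") as fh:
        fh.write(f"# quantity={profile.quantity} units={profile.units} center={profile.center}\n")
        df.to_csv(fh, index=False)
    return path


def sectoral_map_to_csv(smap: SectoralMap, path: str | Path) -> Path:
    """Long-format CSV: one row per (half, r bin, theta bin) cell."""
    path = Path(path)
    rows = []
    for half_name, arr in (("upper", smap.upper), ("lower", smap.lower)):
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                rows.append(
                    {
                        "half": half_name,
                        "r_lo_nm": smap.r_edges[i],
                        "r_hi_nm": smap.r_edges[i + 1],
                        "theta_lo_rad": smap.theta_edges[j],
                        "theta_hi_rad": smap.theta_edges[j + 1],
                        "mass_g_mol": arr[i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
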