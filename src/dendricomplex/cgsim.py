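"""Coarse-grained overdamped Langevin dynamics of dendrimer + fullerene + ions.

The generator emulates, at desk scale, the statistical structure of an
atomistic complexation run: a compact polycation (one bead per residue, the
terminal beads carrying +1 e each), a rigid hydrophobic cage, and explicit
monovalent counterions, all in implicit water inside a periodic box.

Force field
-----------
* harmonic bonds along the dendrimer tree,
* Weeks-Chandler-Andersen (purely repulsive, shifted LJ) excluded volume
  between all bead pairs,
* a short-range Gaussian attraction well between fullerene beads and
  *uncharged* dendrimer beads (the hydrophobic interior) — the terminal
  charged shell feels no attraction, mirroring a solvated cationic corona
  around a hydrophobic core,
* screened Coulomb (Yukawa) interactions between charged beads with a fixed
  Debye length, standing in for explicit-water electrostatics.

Integration is position (overdamped) Langevin: dx = F/gamma dt + sqrt(2
kB T dt / gamma) xi, with per-bead friction gamma_i = m_i * friction. The
fullerene cage moves as one rigid body (overdamped centre-of-mass and
rotational updates); it never deforms. Minimum-image convention is applied
to every pair force; emitted coordinates are *unwrapped*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import BeadConformation, GROUP_COUNTERION, GROUP_DENDRIMER, GROUP_FULLERENE
from .units import KE, kbt

__all__ = ["SimParams", "Trajectory", "simulate", "add_counterions"]

#: chloride mass, g/mol
MASS_CL = 35.45

#: default WCA bead diameters per group, nm
DEFAULT_SIGMA = {
    GROUP_DENDRIMER: 0.40,
    GROUP_FULLERENE: 0.25,
    GROUP_COUNTERION: 0.30,
    "water": 0.30,
}


@dataclass
class SimParams:
    """Integration and force-field parameters (nm / ps / kJ/mol / e units)."""

    timestep: float = 0.002  # ps
    n_steps: int = 10000
    save_every: int = 100
    temperature: float = 300.0  # K
    friction: float = 0.5  # 1/ps; gamma_i = m_i * friction
    bond_k: float = 1000.0  # kJ/mol/nm^2
    bond_length: float = 0.5  # nm
    epsilon_rep: float = 1.0  # kJ/mol, WCA strength
    sigma_by_group: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    epsilon_hp: float = 5.0  # kJ/mol, fullerene<->hydrophobic-bead well depth
    sigma_hp: float = 0.7  # nm, range of the hydrophobic well
    debye_length: float = 0.8  # nm
    dielectric: float = 78.4
    max_drift: float = 0.05  # nm; per-step cap on the deterministic move,
    # prevents overshoot through the steep WCA wall at finite timestep
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "timestep",
            "save_every",
            "friction",
            "bond_k",
            "bond_length",
            "epsilon_rep",
            "sigma_hp",
            "debye_length",
            "dielectric",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.temperature < 0 or self.epsilon_hp < 0:
            raise ValueError("temperature and epsilon_hp must be non-negative")
        if self.timestep * self.friction >= 1.0:
            raise ValueError("stability guard: timestep * friction must be < 1")


@dataclass
class Trajectory:
    """Time-ordered unwrapped bead positions over a fixed particle set."""

    positions: np.ndarray  # (n_frames, n_beads, 3), nm, unwrapped
    times: np.ndarray  # ps
    masses: np.ndarray
    charges: np.ndarray
    groups: np.ndarray
    box: np.ndarray
    metadata: dict = field(default_factory=dict)
    unwrapped: bool = True

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.positions) != len(self.times):
            raise ValueError("positions and times must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def select(self, group: str) -> np.ndarray:
        return np.asarray(self.groups, dtype=object) == group

    def frame(self, i: int) -> BeadConformation:
        return BeadConformation(
            positions=self.positions[i].copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            groups=np.asarray(self.groups, dtype=object).copy(),
            box=self.box.copy(),
        )


def add_counterions(
    system: BeadConformation,
    n: int | None = None,
    seed: int = 0,
    min_distance: float = 0.4,
    max_retries: int = 10000,
) -> BeadConformation:
    """Add n monovalent -1 counterions uniformly at random in the box.

    ``n`` defaults to the total positive charge of the system, which makes
    the combined system electrically neutral.
    """
    if n is None:
        n = int(round(system.charges[system.charges > 0].sum()))
    if n == 0:
        return system.copy()
    rng = np.random.default_rng(seed)
    existing = system.positions.copy()
    placed = []
    for _ in range(n):
        for _ in range(max_retries):
            cand = rng.uniform(0.0, system.box, size=3)
            pool = existing if not placed else np.vstack([existing, placed])
            delta = pool - cand
            delta -= system.box * np.round(delta / system.box)
            if np.min(np.linalg.norm(delta, axis=1)) >= min_distance:
                placed.append(cand)
                break
        else:
            raise RuntimeError(f"counterion placement failed after {max_retries} tries")
    placed = np.asarray(placed)
    names = None
    if system.names is not None:
        names = np.concatenate([system.names, np.array(["CL"] * n, dtype=object)])
    return BeadConformation(
        positions=np.vstack([system.positions, placed]),
        masses=np.concatenate([system.masses, np.full(n, MASS_CL)]),
        charges=np.concatenate([system.charges, np.full(n, -1.0)]),
        groups=np.concatenate(
            [system.groups, np.array([GROUP_COUNTERION] * n, dtype=object)]
        ),
        box=system.box.copy(),
        bonds=list(system.bonds),
        names=names,
    )


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def simulate(system: BeadConformation, params: SimParams) -> Trajectory:
    """Integrate overdamped Langevin dynamics; deterministic for fixed seed.

    The fullerene group (if present) is propagated as a rigid body. Raises
    ``FloatingPointError`` with a diagnostic if coordinates diverge beyond
    100 box lengths.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = system.n_beads
    pos = system.positions.astype(float).copy()
    box = system.box.astype(float)
    masses = system.masses
    charges = system.charges
    groups = np.asarray(system.groups, dtype=object)

    gamma = masses * params.friction
    kT = kbt(params.temperature)

    # ---- bonded terms
    bonds = []
    for b in system.bonds:
        i, j, r0, k = b if len(b) == 4 else (b[0], b[1], None, None)
        bonds.append((i, j, params.bond_length if r0 is None else r0,
                      params.bond_k if k is None else k))
    if bonds:
        bi = np.array([b[0] for b in bonds])
        bj = np.array([b[1] for b in bonds])
        br0 = np.array([b[2] for b in bonds])
        bk = np.array([b[3] for b in bonds])

    # ---- pair bookkeeping
    ii, jj = _pair_indices(n)
    sigma_bead = np.array(
        [params.sigma_by_group.get(g, 0.35) for g in groups], dtype=float
    )
    sigma_pair = 0.5 * (sigma_bead[ii] + sigma_bead[jj])
    wca_cut = sigma_pair * 2.0 ** (1.0 / 6.0)
    is_ful = groups == GROUP_FULLERENE
    is_hydrophobic = (groups == GROUP_DENDRIMER) & (charges == 0.0)
    hp_mask = (is_ful[ii] & is_hydrophobic[jj]) | (is_ful[jj] & is_hydrophobic[ii])
    qq = charges[ii] * charges[jj]
    charged_mask = qq != 0.0
    hp_cut = 3.0 * params.sigma_hp
    yk_cut = 5.0 * params.debye_length
    ke_eff = KE / params.dielectric

    # ---- rigid fullerene bookkeeping
    ful_idx = np.where(is_ful)[0]
    rigid = ful_idx.size > 0
    if rigid:
        ful_m = masses[ful_idx]
        ful_com = (ful_m[:, None] * pos[ful_idx]).sum(0) / ful_m.sum()
        body = pos[ful_idx] - ful_com  # body-frame coordinates
        orient = np.eye(3)
        gamma_t = gamma[ful_idx].sum()
        gamma_r = (gamma[ful_idx] * (body**2).sum(1)).sum()
        mobile = np.setdiff1d(np.arange(n), ful_idx)
    else:
        mobile = np.arange(n)

    inv_gamma = 1.0 / gamma[mobile]
    noise_amp = np.sqrt(2.0 * kT * params.timestep * inv_gamma)

    n_saved = params.n_steps // params.save_every + 1
    out = np.empty((n_saved, n, 3))
    times = np.empty(n_saved)
    out[0] = pos
    times[0] = 0.0
    save_k = 1

    dt = params.timestep
    for step in range(1, params.n_steps + 1):
        forces = np.zeros_like(pos)

        # pair forces with minimum image
        d = pos[jj] - pos[ii]
        d -= box * np.round(d / box)
        r2 = (d * d).sum(1)
        r = np.maximum(np.sqrt(r2), 1e-12)
        fmag = np.zeros_like(r)  # dU/dr; positive = repulsive

        # WCA
        in_rep = r < wca_cut
        if np.any(in_rep):
            sr6 = (sigma_pair[in_rep] / r[in_rep]) ** 6
            # f = 24 eps (2 sr12 - sr6)/r, repulsive branch only
            fmag[in_rep] += 24.0 * params.epsilon_rep * (2.0 * sr6**2 - sr6) / r[in_rep]

        # hydrophobic Gaussian well (attractive): U = -eps exp(-(r/s)^2)
        if params.epsilon_hp > 0.0:
            m = hp_mask & (r < hp_cut)
            if np.any(m):
                s2 = params.sigma_hp**2
                fmag[m] += (
                    -2.0 * params.epsilon_hp * r[m] / s2 * np.exp(-r2[m] / s2)
                )

        # screened Coulomb
        m = charged_mask & (r < yk_cut)
        if np.any(m):
            lam = params.debye_length
            expf = np.exp(-r[m] / lam)
            fmag[m] += ke_eff * qq[m] * expf * (1.0 / r2[m] + 1.0 / (lam * r[m]))

        fvec = (fmag / r)[:, None] * d  # force on j along +d, on i along -d
        for k in range(3):
            forces[:, k] = np.bincount(jj, fvec[:, k], minlength=n) - np.bincount(
                ii, fvec[:, k], minlength=n
            )

        # bonds
        if bonds:
            db = pos[bj] - pos[bi]
            db -= box * np.round(db / box)
            rb = np.maximum(np.linalg.norm(db, axis=1), 1e-12)
            fb = (-bk * (rb - br0) / rb)[:, None] * db
            for k in range(3):
                forces[:, k] += np.bincount(bj, fb[:, k], minlength=n) - np.bincount(
                    bi, fb[:, k], minlength=n
                )

        # mobile beads: overdamped update with drift cap
        drift = forces[mobile] * (dt * inv_gamma[:, None])
        dnorm = np.linalg.norm(drift, axis=1)
        over = dnorm > params.max_drift
        if np.any(over):
            drift[over] *= (params.max_drift / dnorm[over])[:, None]
        xi = rng.standard_normal((mobile.size, 3))
        pos[mobile] += drift + noise_amp[:, None] * xi

        # rigid fullerene: COM + rotation update
        if rigid:
            fnet = forces[ful_idx].sum(0)
            arms = pos[ful_idx] - ful_com
            torque = np.cross(arms, forces[ful_idx]).sum(0)
            com_drift = fnet * (dt / gamma_t)
            cn = np.linalg.norm(com_drift)
            if cn > params.max_drift:
                com_drift *= params.max_drift / cn
            ful_com = (
                ful_com
                + com_drift
                + np.sqrt(2.0 * kT * dt / gamma_t) * rng.standard_normal(3)
            )
            dtheta = torque * (dt / gamma_r) + np.sqrt(
                2.0 * kT * dt / gamma_r
            ) * rng.standard_normal(3)
            angle = np.linalg.norm(dtheta)
            if angle > 0.0:
                ax = dtheta / angle
                K = np.array(
                    [[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]]
                )
                rotstep = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
                orient = rotstep @ orient
            if step % 200 == 0:  # keep orientation orthonormal
                u, _, vt = np.linalg.svd(orient)
                orient = u @ vt
            pos[ful_idx] = ful_com + body @ orient.T

        if step % params.save_every == 0:
            if np.any(np.abs(pos - box / 2.0) > 100.0 * box.max()):
                raise FloatingPointError(
                    f"coordinates diverged at step {step} "
                    f"(max |x| = {np.abs(pos).max():.3g} nm); reduce the "
                    "timestep or the force constants"
                )
            out[save_k] = pos
            times[save_k] = step * dt
            save_k += 1

    return Trajectory(
        positions=out,
        times=times,
        masses=masses.copy(),
        charges=charges.copy(),
        groups=groups.copy(),
        box=box.copy(),
        metadata={"params": asdict(params), "seed": params.seed},
        unwrapped=True,
    )
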