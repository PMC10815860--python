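import dataclasses

import numpy as np
import pytest

from dendricomplex import SimParams, build_system, simulate
from dendricomplex.cgsim import Trajectory

#: desk-scale study conditions shared by the end-to-end stochastic tests:
#: lysG2 + C60 in a 5 nm box, guest offset 2.0 nm, 15000 steps of 2 fs
CG_SEEDS = (1, 2, 3, 4, 5)
CG_BOX = 5.0
CG_OFFSET = 2.0
CG_STEPS = 15000


def _params(seed: int, **overrides) -> SimParams:
    return SimParams(n_steps=CG_STEPS, save_every=100, seed=seed, **overrides)


@pytest.fixture(scope="session")
def cg_runs():
    """Matched CG trajectories per seed: complex, no-attraction control,
    and dendrimer-alone, reused by every stochastic end-to-end test."""
    runs = {}
    for seed in CG_SEEDS:
        system = build_system(
            "lysG2", 60, box=CG_BOX, offset=CG_OFFSET, axis="x", seed=seed
        )
        alone = build_system("lysG2", None, box=CG_BOX, seed=seed)
        runs[seed] = {
            "complex": simulate(system, _params(seed)),
            "control": simulate(system, _params(seed, epsilon_hp=0.0)),
            "alone": simulate(alone, _params(seed)),
        }
    return runs


def make_trajectory(
    positions, masses=None, charges=None, groups=None, box=100.0, times=None
) -> Trajectory:
    """Build a small synthetic Trajectory from raw frame positions."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    n = positions.shape[1]
    return Trajectory(
        positions=positions,
        times=np.arange(positions.shape[0], dtype=float) if times is None else times,
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        groups=np.array(["dendrimer"] * n, dtype=object) if groups is None else np.asarray(groups, dtype=object),
        box=np.broadcast_to(np.atleast_1d(np.asarray(box, float)), (3,)).copy(),
    )
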