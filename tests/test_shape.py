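import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendricomplex.shape import (
    NOT_FORMED,
    TimeSeries,
    com_distance,
    detect_complexation,
    gyration_summary,
    radius_of_gyration,
    rg_distribution,
    rg_series,
    unwrap_cluster,
)
from tests.conftest import make_trajectory


def brute_force_rg(positions, masses):
    """Independent oracle: double loop over the pairwise-distance identity
    Rg^2 = sum_ij m_i m_j |r_i - r_j|^2 / (2 M^2)."""
    M = masses.sum()
    acc = 0.0
    for i in range(len(positions)):
        for j in range(len(positions)):
            acc += masses[i] * masses[j] * np.sum((positions[i] - positions[j]) ** 2)
    return np.sqrt(acc / (2.0 * M**2))


def brute_force_alpha(positions, masses):
    """Independently coded gyration-tensor eigenvalue oracle."""
    com = np.average(positions, axis=0, weights=masses)
    dx = positions - com
    S = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            S[a, b] = np.sum(masses * dx[:, a] * dx[:, b]) / masses.sum()
    lam = np.sort(np.linalg.eigvals(S).real)[::-1]
    i1 = lam.sum()
    i2 = lam[0] * lam[1] + lam[1] * lam[2] + lam[0] * lam[2]
    return 1.0 - 3.0 * i2 / i1**2


class TestComDistance:
    def test_identical_selections_give_zero(self):
        traj = make_trajectory(np.random.default_rng(0).uniform(0, 5, (4, 6, 3)))
        d = com_distance(traj, None, None)
        assert np.allclose(d.values, 0.0)

    def test_plain_distance(self):
        traj = make_trajectory(
            [[[0.0, 0, 0], [1.0, 0, 0]]], groups=["dendrimer", "fullerene"], box=10.0
        )
        d = com_distance(traj, "dendrimer", "fullerene")
        assert d.values[0] == pytest.approx(1.0)

    def test_minimum_image(self):
        traj = make_trajectory(
            [[[0.0, 0, 0], [9.0, 0, 0]]], groups=["dendrimer", "fullerene"], box=10.0
        )
        d = com_distance(traj, "dendrimer", "fullerene")
        assert d.values[0] == pytest.approx(1.0)

    def test_empty_selection_rejected(self):
        traj = make_trajectory([[[0.0, 0, 0]]])
        with pytest.raises(ValueError):
            com_distance(traj, "dendrimer", "fullerene")


class TestRadiusOfGyration:
    def test_single_bead_is_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2, 3]]), np.array([5.0])) == 0.0

    def test_two_equal_masses(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pos, np.ones(2)) == pytest.approx(1.0)

    def test_against_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(2, 51)
            pos = rng.uniform(-3, 3, (n, 3))
            masses = rng.uniform(0.5, 200.0, n)
            assert radius_of_gyration(pos, masses) == pytest.approx(
                brute_force_rg(pos, masses), rel=1e-12
            )

    def test_rg_squared_equals_tensor_trace(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pos = rng.normal(0, 1.5, (30, 3))
            masses = rng.uniform(1, 50, 30)
            rg = radius_of_gyration(pos, masses)
            summary = gyration_summary(pos, masses)
            assert rg**2 == pytest.approx(summary.I1, rel=1e-9)


class TestAsphericity:
    def test_collinear_is_exactly_one(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(-2, 2, 15)
        direction = np.array([1.0, -2.0, 0.5])
        pos = np.outer(t, direction)
        summary = gyration_summary(pos, rng.uniform(0.1, 10, 15))
        assert summary.alpha == 1.0

    def test_uniform_sphere_surface_is_nearly_zero(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(10_000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        summary = gyration_summary(v, np.ones(len(v)))
        assert summary.alpha < 0.02

    def test_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(0, 1, (20, 3))
        masses = rng.uniform(0.5, 3.0, 20)
        summary = gyration_summary(pos, masses)
        assert summary.alpha == pytest.approx(brute_force_alpha(pos, masses), abs=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariance_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 1, (12, 3))
        masses = rng.uniform(0.5, 5.0, 12)
        a0 = gyration_summary(pos, masses).alpha
        # random rotation via QR, plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pos @ q.T + rng.uniform(-10, 10, 3)
        assert gyration_summary(moved, masses).alpha == pytest.approx(a0, abs=1e-10)

    def test_degenerate_flagged(self):
        pos = np.zeros((5, 3))
        summary = gyration_summary(pos, np.ones(5))
        assert summary.degenerate
        assert np.isnan(summary.alpha)

    def test_eigenvalues_sum_to_rg_squared(self):
        rng = np.random.default_rng(13)
        pos = rng.normal(0, 2, (40, 3))
        masses = rng.uniform(1, 10, 40)
        s = gyration_summary(pos, masses)
        assert sum(s.eigenvalues) == pytest.approx(s.Rg**2, rel=1e-9)
        assert s.eigenvalues[0] >= s.eigenvalues[1] >= s.eigenvalues[2] >= 0


class TestRgDistribution:
    def test_constant_conformation_single_bin(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        traj = make_trajectory(np.repeat(pos[None], 10, axis=0))
        hist = rg_distribution(traj, bin_width=0.05)
        assert (hist.probabilities > 0).sum() == 1

    def test_two_state_series_is_bimodal_with_equal_mass(self):
        compact = np.array([[0.0, 0, 0], [1.0, 0, 0]])  # Rg 0.5
        extended = np.array([[0.0, 0, 0], [2.0, 0, 0]])  # Rg 1.0
        frames = np.array([compact, extended] * 25)
        traj = make_trajectory(frames)
        hist = rg_distribution(traj, bin_width=0.1)
        occupied = np.where(hist.probabilities > 0)[0]
        assert len(occupied) == 2
        masses = hist.probabilities[occupied] * np.diff(hist.edges)[occupied]
        assert masses[0] == pytest.approx(0.5, abs=0.02)
        assert masses[1] == pytest.approx(0.5, abs=0.02)

    def test_narrower_input_gives_smaller_std(self):
        rng = np.random.default_rng(21)
        def traj_with_noise(scale):
            base = np.array([[0.0, 0, 0], [1.5, 0, 0]])
            frames = base[None] + rng.normal(0, scale, (200, 2, 3))
            return make_trajectory(frames)
        wide = rg_distribution(traj_with_noise(0.3), bin_width=0.02)
        narrow = rg_distribution(traj_with_noise(0.05), bin_width=0.02)
        assert narrow.std() < wide.std()


class TestDetection:
    def test_step_function_detected_at_step_time(self):
        times = np.arange(0.0, 400.0, 4.0)
        values = np.where(times < 100.0, 5.0, 0.8)
        t = detect_complexation(
            TimeSeries(times, values), threshold=1.2, hold=50.0, smooth_window=1
        )
        assert t == pytest.approx(100.0, abs=4.0)

    def test_never_below_threshold(self):
        times = np.arange(0.0, 100.0, 1.0)
        ts = TimeSeries(times, np.linspace(5.0, 2.0, len(times)))
        assert detect_complexation(ts, threshold=1.2, hold=10.0) == NOT_FORMED

    def test_short_dip_not_counted(self):
        times = np.arange(0.0, 100.0, 1.0)
        values = np.full(len(times), 5.0)
        values[40:45] = 0.5  # 5 ps dip, hold demands 20 ps
        ts = TimeSeries(times, values)
        assert detect_complexation(ts, threshold=1.2, hold=20.0, smooth_window=1) == NOT_FORMED

    def test_hold_longer_than_series_rejected(self):
        ts = TimeSeries(np.arange(0.0, 10.0), np.ones(10))
        with pytest.raises(ValueError):
            detect_complexation(ts, threshold=1.0, hold=100.0)


class TestUnwrap:
    def test_bonded_chain_unwrapped_across_boundary(self):
        box = np.array([10.0, 10.0, 10.0])
        # chain 9.6 - 0.4 - 1.2: wrapped jump between beads 0 and 1
        pos = np.array([[9.6, 5, 5], [0.4, 5, 5], [1.2, 5, 5]])
        bonds = [(0, 1), (1, 2)]
        un = unwrap_cluster(pos, box, bonds)
        d01 = np.linalg.norm(un[1] - un[0])
        d12 = np.linalg.norm(un[2] - un[1])
        assert d01 == pytest.approx(0.8)
        assert d12 == pytest.approx(0.8)
        assert radius_of_gyration(un, np.ones(3)) < 1.0


class TestComplexNarrowing:
    def test_complex_rg_fluctuations_narrower_than_dendrimer_alone(self, cg_runs):
        """With strong attraction the rigid guest glues the branches: the
        pooled Rg variance of the complex is below the dendrimer-alone one."""
        ratios = []
        for seed, runs in cg_runs.items():
            tr = runs["complex"]
            lo = tr.n_frames // 2
            sel = tr.select("dendrimer") | tr.select("fullerene")
            v_complex = rg_series(tr, sel).values[lo:].var()
            alone = runs["alone"]
            v_alone = rg_series(alone, "dendrimer").values[lo:].var()
            ratios.append(v_complex / v_alone)
        assert np.mean(ratios) < 1.0
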