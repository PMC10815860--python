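import numpy as np
import pytest

from dendricomplex.electrostatics import (
    cumulative_charge,
    electrostatic_profile,
    radial_charge,
    solve_poisson,
    zeta_potential,
)
from dendricomplex.fields import RadialProfile
from dendricomplex.pipeline import build_system
from dendricomplex.units import KE_MV
from tests.conftest import make_trajectory


def shell_profile(edges, charges_per_shell):
    return RadialProfile(edges, charges_per_shell, "charge", "e")


class TestRadialCharge:
    def test_single_charge_in_one_shell(self):
        traj = make_trajectory(
            [[[5.0, 5, 5], [5.63, 5, 5]]],
            masses=[1.0, 1.0],
            charges=[0.0, 1.0],
            groups=["fullerene", "dendrimer"],
        )
        q = radial_charge(traj, "dendrimer", "fullerene", bin_width=0.1)
        occupied = np.where(q.values != 0)[0]
        assert list(occupied) == [6]
        assert q.values.sum() == pytest.approx(1.0)

    def test_neutral_system_sums_to_zero(self):
        system = build_system("lysG2", 60, box=5.0, offset=2.0, seed=2)
        traj = make_trajectory(
            [system.positions],
            masses=system.masses,
            charges=system.charges,
            groups=system.groups,
            box=5.0,
        )
        q = radial_charge(
            traj, ["dendrimer", "fullerene", "counterion"], "dendrimer", bin_width=0.1
        )
        assert q.values.sum() == pytest.approx(0.0, abs=1e-12)

    def test_dendrimer_only_charge_is_bare_charge(self):
        system = build_system("lysG3", None, box=6.0, seed=1)
        traj = make_trajectory(
            [system.positions],
            masses=system.masses,
            charges=system.charges,
            groups=system.groups,
            box=6.0,
        )
        q = radial_charge(traj, "dendrimer", "dendrimer", bin_width=0.1)
        assert q.values.sum() == pytest.approx(32.0)


class TestCumulativeCharge:
    def test_all_positive_shells(self):
        prof = shell_profile(np.linspace(0, 1, 6), np.full(5, 2.0))
        Q, q_max, r_at = cumulative_charge(prof)
        assert q_max == pytest.approx(10.0)
        assert r_at == pytest.approx(1.0)
        assert np.all(np.diff(Q) >= 0)

    def test_inner_positive_outer_negative(self):
        edges = np.linspace(0, 2.0, 21)
        q = np.zeros(20)
        q[:10] = 1.6   # +16 inside r < 1
        q[10:] = -1.6  # -16 outside
        Q, q_max, r_at = cumulative_charge(shell_profile(edges, q))
        assert q_max == pytest.approx(16.0)
        assert r_at == pytest.approx(1.0)
        assert Q[-1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_charges(self):
        _, q_max, _ = cumulative_charge(shell_profile(np.linspace(0, 1, 4), np.zeros(3)))
        assert q_max == 0.0


class TestPoissonSolver:
    def test_zero_charge_gives_zero_potential(self):
        prof = shell_profile(np.linspace(0, 3, 500), np.zeros(499))
        psi = solve_poisson(prof)
        assert np.allclose(psi, 0.0)

    def test_charged_shell_closed_form(self):
        # total charge Q on a thin shell at a = 1 nm, coulomb-tail BC:
        # outside psi = k Q / (eps r); inside constant k Q / (eps a)
        edges = np.linspace(0.0, 3.0, 1001)
        q = np.zeros(1000)
        a, Qtot, eps = 1.0, 8.0, 78.4
        shell_idx = np.searchsorted(edges, a) - 1
        q[shell_idx] = Qtot
        psi = solve_poisson(shell_profile(edges, q), dielectric=eps)
        r = edges[1:]
        outside = r > a * 1.05
        expected_out = KE_MV * Qtot / (eps * r[outside])
        assert np.allclose(psi[outside], expected_out, rtol=0.01)
        inside = r < a * 0.95
        expected_in = KE_MV * Qtot / (eps * a)
        assert np.allclose(psi[inside], expected_in, rtol=0.01)

    def test_uniform_ball_closed_form(self):
        # uniformly charged ball radius a: inside
        # psi(r) = k Q (3 - r^2/a^2) / (2 eps a); outside Coulomb
        a, Qtot, eps = 1.0, 10.0, 78.4
        edges = np.linspace(0.0, 3.0, 2001)
        q = np.zeros(2000)
        inside_shells = edges[1:] <= a
        vol = np.diff(edges**3)
        q[inside_shells] = Qtot * vol[inside_shells] / a**3
        psi = solve_poisson(shell_profile(edges, q), dielectric=eps)
        r = edges[1:]
        sel_in = r <= a
        expected_in = KE_MV * Qtot * (3.0 - r[sel_in] ** 2 / a**2) / (2.0 * eps * a)
        assert np.allclose(psi[sel_in], expected_in, rtol=0.01)
        sel_out = r > a
        assert np.allclose(psi[sel_out], KE_MV * Qtot / (eps * r[sel_out]), rtol=0.01)

    def test_first_order_grid_convergence(self):
        a, Qtot, eps = 1.0, 5.0, 78.4

        def max_error(n):
            edges = np.linspace(0.0, 3.0, n + 1)
            q = np.zeros(n)
            vol = np.diff(edges**3)
            inside = edges[1:] <= a
            q[inside] = Qtot * vol[inside] / a**3
            psi = solve_poisson(shell_profile(edges, q), dielectric=eps)
            r = edges[1:]
            exact = np.where(
                r <= a,
                KE_MV * Qtot * (3.0 - r**2 / a**2) / (2.0 * eps * a),
                KE_MV * Qtot / (eps * r),
            )
            return np.abs(psi - exact).max()

        errs = [max_error(n) for n in (300, 600, 1200)]
        assert errs[1] < errs[0]
        assert errs[2] < errs[1]
        # at least first order: halving the bin width at least halves the
        # error (with 25% slack for the non-smooth ball edge)
        assert errs[2] < 0.75 * errs[0]

    def test_superposition_linearity(self):
        rng = np.random.default_rng(17)
        edges = np.linspace(0.0, 2.0, 401)
        q1 = rng.normal(0, 1, 400)
        q2 = rng.normal(0, 1, 400)
        p1 = solve_poisson(shell_profile(edges, q1))
        p2 = solve_poisson(shell_profile(edges, q2))
        p12 = solve_poisson(shell_profile(edges, q1 + q2))
        scale = np.abs(p12).max()
        assert np.allclose(p12, p1 + p2, atol=1e-9 * max(scale, 1.0))

    def test_boundary_conditions_and_validation(self):
        edges = np.linspace(0.0, 2.0, 101)
        q = np.zeros(100)
        q[10] = 4.0
        psi_zero = solve_poisson(shell_profile(edges, q), boundary="zero-at-R")
        psi_tail = solve_poisson(shell_profile(edges, q), boundary="coulomb-tail")
        assert psi_zero[-1] == pytest.approx(0.0)
        offset = KE_MV * 4.0 / (78.4 * 2.0)
        assert np.allclose(psi_tail - psi_zero, offset)
        with pytest.raises(ValueError):
            solve_poisson(shell_profile(edges, q), dielectric=-1.0)
        with pytest.raises(ValueError):
            solve_poisson(shell_profile(edges, q), boundary="bogus")


class TestZetaPotential:
    def test_zero_potential_gives_zero_zeta(self):
        edges = np.linspace(0.0, 2.0, 101)
        prof = shell_profile(edges, np.zeros(100))
        psi = solve_poisson(prof)
        for surface, kwargs in (
            ("at-Qmax-radius", {}),
            ("at-fixed-r", {"fixed_r": 1.0}),
        ):
            zeta, _ = zeta_potential(psi, prof, surface, **kwargs)
            assert zeta == 0.0

    def test_charged_shell_zeta_inside_is_plateau(self):
        edges = np.linspace(0.0, 3.0, 1001)
        q = np.zeros(1000)
        a, Qtot, eps = 1.0, 8.0, 78.4
        q[np.searchsorted(edges, a) - 1] = Qtot
        prof = shell_profile(edges, q)
        psi = solve_poisson(prof, dielectric=eps)
        zeta, _ = zeta_potential(psi, prof, "at-fixed-r", fixed_r=0.5)
        assert zeta == pytest.approx(KE_MV * Qtot / (eps * a), rel=0.01)

    def test_monotone_psi_larger_surface_smaller_zeta(self):
        edges = np.linspace(0.0, 3.0, 301)
        q = np.zeros(300)
        q[50] = 5.0
        prof = shell_profile(edges, q)
        psi = solve_poisson(prof)
        z1, _ = zeta_potential(psi, prof, "at-fixed-r", fixed_r=1.0)
        z2, _ = zeta_potential(psi, prof, "at-fixed-r", fixed_r=2.0)
        assert z2 < z1

    def test_surface_outside_grid_rejected(self):
        edges = np.linspace(0.0, 1.0, 11)
        prof = shell_profile(edges, np.ones(10))
        psi = solve_poisson(prof)
        with pytest.raises(ValueError):
            zeta_potential(psi, prof, "at-fixed-r", fixed_r=5.0)


class TestZetaContrast:
    def test_complex_zeta_exceeds_dendrimer_alone(self, cg_runs):
        """Guest encapsulation densifies the interior and expels counterions:
        the pooled zeta of the complex exceeds the dendrimer-alone control."""
        ratios = []
        for seed, runs in cg_runs.items():
            tr = runs["complex"]
            lo = tr.n_frames // 2
            es_c = electrostatic_profile(
                tr, center_selection="dendrimer", window=(lo, tr.n_frames)
            )
            al = runs["alone"]
            lo = al.n_frames // 2
            es_a = electrostatic_profile(
                al, center_selection="dendrimer", window=(lo, al.n_frames)
            )
            ratios.append(es_c.zeta / es_a.zeta)
        assert np.mean(ratios) > 1.0
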