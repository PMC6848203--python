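"""Force field: bonded terms, shifted nonbonded, tables, pair engine."""

import io

import numpy as np
import pytest

from conftest import assert_forces_match_gradient, numerical_gradient
from lbmd.forcefield import (AngleTerm, BeadType, BondTerm, NonbondedParams,
                             ParameterSet, Topology, angle_energy_forces,
                             bond_energy_forces, build_table, lj_energy_force,
                             pair_energy_force, switched_coulomb)
from lbmd.forcefield.field import ForceField
from lbmd.state import ParticleState

BOX = np.array([60.0, 60.0, 60.0])


def dimer_state(r, box=BOX):
    return ParticleState(np.array([[10.0, 10.0, 10.0], [10.0 + r, 10.0, 10.0]]),
                         box)


class TestBonds:
    def test_minimum_has_zero_energy_and_force(self):
        e, f = bond_energy_forces(dimer_state(4.7), [BondTerm(0, 1, 4.7, 3.0)])
        assert e == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_harmonic_value(self):
        e, _ = bond_energy_forces(dimer_state(5.7), [BondTerm(0, 1, 4.7, 3.0)])
        assert e == pytest.approx(1.5)

    def test_energy_nonnegative_and_spans_pbc(self):
        # bond across the periodic boundary uses the minimum image
        st = ParticleState(np.array([[1.0, 0, 0], [59.0, 0, 0]]), BOX)
        e, _ = bond_energy_forces(st, [BondTerm(0, 1, 2.0, 3.0)])
        assert e == pytest.approx(0.0)  # minimum-image distance is 2.0

    def test_overlap_raises_naming_pair(self):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            bond_energy_forces(dimer_state(0.0), [BondTerm(0, 1, 4.7, 3.0)])

    def test_forces_match_finite_difference(self, rng):
        pos = np.array([[10.0, 10, 10], [13.9, 11.2, 9.1]]) + rng.normal(0, 0.3, (2, 3))
        terms = [BondTerm(0, 1, 4.7, 3.0)]

        def energy(x):
            return bond_energy_forces(ParticleState(x.copy(), BOX), terms)[0]

        _, f = bond_energy_forces(ParticleState(pos.copy(), BOX), terms)
        num = numerical_gradient(energy, pos)
        np.testing.assert_allclose(f, num, rtol=1e-6, atol=1e-9)


class TestAngles:
    @staticmethod
    def triple_state(theta_deg, r=4.7):
        th = np.radians(theta_deg)
        pos = np.array([[r, 0, 0], [0, 0, 0],
                        [r * np.cos(th), r * np.sin(th), 0]]) + 20.0
        return ParticleState(pos, BOX)

    def test_g96_minimum_at_theta0(self):
        e, f = angle_energy_forces(self.triple_state(120.0),
                                   [AngleTerm(0, 1, 2, 120.0, 6.0)])
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_g96_value_at_right_angle(self):
        # θ0 = 180°, θ = 90°: U = ½·25·(cos 90 − cos 180)² = 12.5
        e, _ = angle_energy_forces(self.triple_state(90.0),
                                   [AngleTerm(0, 1, 2, 180.0, 25.0)])
        assert e == pytest.approx(12.5)

    def test_cos_squared_dialect_value(self):
        # ½ K cos²(θ − θ0) exactly as printed (its minimum is 90° off θ0)
        e, _ = angle_energy_forces(
            self.triple_state(60.0),
            [AngleTerm(0, 1, 2, 180.0, 25.0, form="cos_squared")])
        assert e == pytest.approx(0.5 * 25.0 * np.cos(np.radians(60 - 180)) ** 2)

    @pytest.mark.parametrize("form", ["g96_cosine", "cos_squared"])
    def test_forces_match_finite_difference(self, rng, form):
        terms = [AngleTerm(0, 1, 2, 115.0, 6.0, form=form)]
        for _ in range(5):
            pos = 20.0 + rng.normal(0, 3.0, (3, 3))

            def energy(x):
                return angle_energy_forces(ParticleState(x.copy(), BOX), terms)[0]

            st = ParticleState(pos.copy(), BOX)
            _, f = angle_energy_forces(st, terms)
            num = numerical_gradient(energy, pos)
            scale = max(np.max(np.abs(f)), 1.0)
            np.testing.assert_allclose(f, num, atol=1e-6 * scale)

    def test_collinear_triple_clamps_force(self, caplog):
        pos = np.array([[0, 0, 0], [4.7, 0, 0], [9.4, 0, 0]]) + 20.0
        st = ParticleState(pos, BOX)
        with caplog.at_level("WARNING"):
            _, f = angle_energy_forces(
                st, [AngleTerm(0, 1, 2, 90.0, 6.0, form="cos_squared")])
        assert np.all(np.isfinite(f))
        np.testing.assert_allclose(f, 0.0)


class TestSwitchedCoulomb:
    PARAMS = NonbondedParams(dielectric=15.0, cutoff=12.0)
    # frozen from a symbolic differentiation oracle of
    # Φ(r) = 1/r + 5r³/(3r_c⁴) − r⁴/r_c⁵ − 5/(3r_c), scaled by k_e/ε_r
    U_119 = 3.558713628394314e-06
    F_119 = 1.0676291037215818e-04

    def test_zero_at_cutoff(self):
        u, f = switched_coulomb(12.0, 1.0, self.PARAMS)
        assert u == 0.0 and f == 0.0

    def test_beyond_cutoff_zero(self):
        u, f = switched_coulomb(13.5, 1.0, self.PARAMS)
        assert u == 0.0 and f == 0.0

    def test_bare_coulomb_limit_at_small_r(self):
        from lbmd.units import COULOMB

        r = 0.001
        u, _ = switched_coulomb(r, 1.0, self.PARAMS)
        assert u == pytest.approx(COULOMB / 15.0 / r, rel=1e-3)

    def test_values_near_cutoff_match_symbolic_oracle(self):
        u, f = switched_coulomb(11.9, 1.0, self.PARAMS)
        assert u == pytest.approx(self.U_119, rel=1e-9)
        assert f == pytest.approx(self.F_119, rel=1e-9)

    def test_r_zero_raises(self):
        with pytest.raises(ValueError):
            switched_coulomb(0.0, 1.0, self.PARAMS)

    def test_continuously_differentiable(self):
        # F must equal −dU/dr inside the cutoff
        r = np.linspace(1.0, 11.99, 400)
        u, f = switched_coulomb(r, 1.0, self.PARAMS)
        num = -np.gradient(u, r)
        np.testing.assert_allclose(f[5:-5], num[5:-5],
                                   rtol=1e-3, atol=1e-6 * np.abs(f).max())


class TestLennardJones:
    def test_zero_at_cutoff(self):
        u, f = lj_energy_force(12.0, 4.7, 0.5, 12.0)
        assert u == 0.0 and f == 0.0

    def test_unshifted_minimum_depth(self):
        r_min = 2 ** (1 / 6) * 4.7
        u, f = lj_energy_force(r_min, 4.7, 1.0, 12.0, shifted=False)
        assert u == pytest.approx(-1.0)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_shifted_value_matches_coefficient_oracle(self):
        # independent reconstruction from the shift-polynomial coefficients
        sigma, eps, rc, r = 4.7, 0.5, 12.0, 6.0
        c12, c6 = 4 * eps * sigma**12, 4 * eps * sigma**6

        def phi(alpha):
            A = -alpha * (alpha + 4) / rc ** (alpha + 3)
            B = alpha * (alpha + 3) / rc ** (alpha + 4)
            C = -(rc**-alpha - A / 3 * rc**3 - B / 4 * rc**4)
            return r**-alpha - A / 3 * r**3 - B / 4 * r**4 + C

        expected = c12 * phi(12) - c6 * phi(6)
        u, _ = lj_energy_force(r, sigma, eps, rc)
        assert u == pytest.approx(expected, rel=1e-12)

    def test_monotonically_repulsive_below_minimum(self):
        r = np.linspace(3.0, 2 ** (1 / 6) * 4.7, 100)
        u, f = lj_energy_force(r, 4.7, 0.5, 12.0)
        assert np.all(np.diff(u) < 0)
        assert np.all(f[:-1] > 0)


class TestTables:
    def test_neutral_pair_equals_pure_shifted_lj(self):
        p = NonbondedParams(4.7, 0.5)
        tab = build_table(p, q1q2=0.0, spacing=0.01)
        u_ref, f_ref = lj_energy_force(tab.r, 4.7, 0.5, 12.0)
        np.testing.assert_allclose(tab.U, u_ref, atol=1e-10)
        np.testing.assert_allclose(tab.F, f_ref, atol=1e-10)

    def test_opposite_charges_deepen_the_well(self):
        p = NonbondedParams(4.7, 0.5)
        neutral = build_table(p, 0.0, spacing=0.01)
        charged = build_table(p, -1.0, spacing=0.01)
        mid = (neutral.r > 4.5) & (neutral.r < 7.0)
        assert np.all(charged.U[mid] < neutral.U[mid])

    def test_table_nodes_match_analytic(self):
        p = NonbondedParams(4.7, 0.5)
        tab = build_table(p, q1q2=-1.0, spacing=0.002)
        u, f = pair_energy_force(tab.r, p, -1.0)
        np.testing.assert_allclose(tab.U, u, atol=1e-10)
        np.testing.assert_allclose(tab.F, f, atol=1e-10)

    def test_zero_at_cutoff_invariant(self):
        tab = build_table(NonbondedParams(4.7, 0.5), q1q2=1.0)
        assert tab.U[-1] == pytest.approx(0.0, abs=1e-12)
        assert tab.F[-1] == pytest.approx(0.0, abs=1e-12)

    def test_force_column_consistent_with_energy_gradient(self):
        tab = build_table(NonbondedParams(4.7, 0.5), q1q2=-1.0, spacing=0.002)
        dU = -np.gradient(tab.U, tab.r)
        interior = (tab.r > 2.0) & (tab.r < tab.r[-1] - 0.01)
        # 1e-3 relative, with a small floor near the zero crossing of F
        np.testing.assert_allclose(tab.F[interior], dU[interior],
                                   rtol=1e-3, atol=1e-4)

    def test_interpolation_accuracy_in_well_region(self):
        p = NonbondedParams(4.7, 0.5)
        tab = build_table(p, q1q2=-1.0, spacing=0.002)
        r = np.linspace(0.9 * 4.7, 11.99, 500) + 0.0007
        u_i, _ = tab.evaluate(r)
        u_a, _ = pair_energy_force(r, p, -1.0)
        np.testing.assert_allclose(u_i, u_a, atol=1e-4)

    def test_bad_spacing_raises(self):
        with pytest.raises(ValueError):
            build_table(NonbondedParams(), spacing=0.0)

    def test_text_round_trip(self, tmp_path):
        tab = build_table(NonbondedParams(4.7, 0.5), q1q2=1.0, spacing=0.01)
        path = tmp_path / "table.dat"
        tab.to_text(path)
        back = type(tab).from_text(path)
        np.testing.assert_allclose(back.U, tab.U, rtol=1e-6)


class TestPairEngine:
    def test_isolated_beads_beyond_cutoff(self, toy_params):
        topo = Topology(["T", "T"])
        st = dimer_state(15.0)
        e, f = ForceField(topo, toy_params).nonbonded(st)
        assert e == 0.0
        np.testing.assert_allclose(f, 0.0)

    def test_neighbour_list_equals_all_pairs_oracle(self, toy_params, rng):
        names = ["T", "P", "C"] * 50
        topo = Topology(names, bonds=[BondTerm(0, 1, 4.7, 3.0)])
        topo.build_exclusions()
        st = ParticleState(rng.uniform(0, 75, (150, 3)), np.full(3, 75.0))
        ff = ForceField(topo, toy_params)
        e1, f1 = ff.nonbonded(st)
        e2, f2 = ff.all_pairs(st)
        assert e1 == pytest.approx(e2, rel=1e-10)
        np.testing.assert_allclose(f1, f2, atol=1e-10 * max(1, np.abs(f2).max()))

    def test_excluded_bonded_pair_contributes_nothing(self, toy_params,
                                                      dimer_topology):
        st = dimer_state(2.0)  # r < σ: huge if not excluded
        e, _ = ForceField(dimer_topology, toy_params).nonbonded(st)
        assert e == 0.0

    def test_box_too_small_for_cutoff_raises(self, toy_params):
        topo = Topology(["T", "T"])
        st = dimer_state(5.0, box=np.array([20.0, 20.0, 20.0]))
        with pytest.raises(ValueError, match="too small"):
            ForceField(topo, toy_params).nonbonded(st)

    def test_total_forces_match_finite_difference(self, toy_params, rng):
        names = ["C", "P", "T", "T", "T", "T"]
        topo = Topology(names,
                        bonds=[BondTerm(0, 1, 4.7, 3.0), BondTerm(1, 2, 4.7, 3.0)],
                        angles=[AngleTerm(0, 1, 2, 150.0, 6.0)])
        topo.build_exclusions()
        pos = rng.uniform(20, 40, (6, 3))
        assert_forces_match_gradient(topo, toy_params, pos, BOX)

    def test_newtons_third_law(self, toy_params, rng):
        topo = Topology(["C", "P"] * 20)
        st = ParticleState(rng.uniform(0, 60, (40, 3)), BOX)
        _, f = ForceField(topo, toy_params).nonbonded(st)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)
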