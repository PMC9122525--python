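"""Interaction terms: shapes, switching logic and gradient identities."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from smcsim import forcefield as ff
from smcsim.model_builder import VariantSpec, build_smcc


class TestPairTerm:
    def test_zero_at_cutoff(self):
        term = ff.PairTerm(epsilon=3.2, sigma=2.0, mode="attractive")
        e, f = ff.pair_energy_force(term.rcut, term)
        assert e == 0.0 and f == 0.0

    def test_wca_zero_at_minimum(self):
        term = ff.PairTerm(epsilon=1.0, sigma=2.0, mode="repulsive")
        e, f = ff.pair_energy_force(2 ** (1 / 6) * 2.0, term)
        assert abs(e) < 1e-12
        assert abs(f) < 1e-9

    def test_repulsive_monotone_nonnegative(self):
        term = ff.PairTerm(epsilon=1.0, sigma=2.0, mode="repulsive")
        r = np.linspace(0.8, term.rcut, 200)
        e = np.array([ff.pair_energy_force(x, term)[0] for x in r])
        assert (e >= -1e-12).all()
        assert (np.diff(e) <= 1e-12).all()

    def test_attractive_minimum_depth(self):
        """Numerical minimization: depth = eps minus the cutoff shift."""
        term = ff.PairTerm(epsilon=3.2, sigma=2.227, mode="attractive")
        res = minimize_scalar(lambda r: ff.pair_energy_force(r, term)[0],
                              bounds=(2.0, 4.0), method="bounded",
                              options={"xatol": 1e-10})
        expected = -(term.epsilon + term.shift)
        assert abs(res.fun - expected) < 1e-6
        # the shift is a small correction: depth is eps to within 2%
        assert abs(-res.fun - term.epsilon) < 0.02 * term.epsilon

    def test_mode_swap_changes_only_between_min_and_cutoff(self):
        rep = ff.PairTerm(epsilon=1.0, sigma=2.0, mode="repulsive")
        att = ff.PairTerm(epsilon=1.0, sigma=2.0, mode="attractive")
        rmin = 2 ** (1 / 6) * 2.0
        for r in np.linspace(0.9, rep.rcut * 2.49 / 1.122, 100):
            e_r = ff.pair_energy_force(r, rep)[0]
            e_a = ff.pair_energy_force(r, att)[0]
            if r < rmin:
                # inside the core both act; they differ only by the shift
                assert abs((e_r - e_a) - (att.shift - rep.shift)) < 1e-10
            elif r >= att.rcut:
                assert e_r == e_a == 0.0

    def test_singular_separation(self):
        with pytest.raises(ff.SingularSeparationError):
            ff.pair_energy_force(0.0, ff.PairTerm(1.0, 2.0))


class TestBond:
    def test_rest_length_force_free(self):
        e, f = ff.bond_energy_force(ff.BOND_REST)
        assert e == 0.0 and f == 0.0

    def test_symmetric_about_minimum(self):
        for d in (0.05, 0.1, 0.2):
            ep = ff.bond_energy_force(ff.BOND_REST + d)[0]
            em = ff.bond_energy_force(ff.BOND_REST - d)[0]
            assert ep == pytest.approx(em, rel=1e-12)

    def test_overstretch_signal(self):
        with pytest.raises(ff.OverstretchError):
            ff.bond_energy_force(ff.BOND_REST + ff.BOND_MAX_EXT)

    def test_stiffness_near_minimum(self):
        d = 1e-4
        e = ff.bond_energy_force(ff.BOND_REST + d)[0]
        assert e == pytest.approx(0.5 * ff.BOND_K * d * d, rel=1e-3)


class TestAngle:
    def test_zero_at_equilibrium(self):
        assert ff.angle_energy_force(1.0, 30.0, 1.0) == (0.0, -0.0)

    def test_half_kappa_dtheta_squared(self):
        e, tau = ff.angle_energy_force(math.pi, 30.0, math.pi - 1.0)
        assert e == pytest.approx(15.0)
        assert tau == pytest.approx(-30.0)


class TestDnaCalibration:
    def test_persistence_length_target(self):
        kappa = ff.calibrate_dna_bending_kappa()
        assert ff.persistence_length_of_kappa(kappa) == pytest.approx(
            50.0, abs=1e-6)

    def test_kappa_near_kratky_porod_estimate(self):
        kappa = ff.calibrate_dna_bending_kappa()
        assert 0.9 * 50.0 / 1.7 < kappa < 1.2 * 50.0 / 1.7


class TestInteractionTable:
    @pytest.fixture(scope="class")
    def geom(self):
        return build_smcc()

    def test_state0_bottom_only(self, geom):
        t = ff.assemble_interaction_table(geom, 0)
        assert t.pair_eps_att[ff.CLASS_BOT_ATT] == 11.0
        assert t.pair_eps_att[ff.CLASS_TOP_ATT] == 0.0
        assert t.pair_eps_att[ff.CLASS_MID_ATT] == 0.0
        assert not t.bridge_on
        assert t.pair_eps_rep[ff.CLASS_BRIDGE_REP] == 0.0

    def test_state1_all_sites_and_bridge(self, geom):
        t = ff.assemble_interaction_table(geom, 1)
        assert t.pair_eps_att[ff.CLASS_TOP_ATT] == 3.2
        assert t.pair_eps_att[ff.CLASS_MID_ATT] == 3.2
        assert t.pair_eps_att[ff.CLASS_BOT_ATT] == 11.0
        assert t.bridge_on
        assert t.pair_eps_rep[ff.CLASS_BRIDGE_REP] == 1.0

    def test_state2_top_survives(self, geom):
        t = ff.assemble_interaction_table(geom, 2)
        assert t.pair_eps_att[ff.CLASS_TOP_ATT] == 3.2
        assert t.pair_eps_att[ff.CLASS_MID_ATT] == 0.0
        assert t.pair_eps_att[ff.CLASS_BOT_ATT] == 0.0
        assert not t.bridge_on

    def test_variant_deactivations(self, geom):
        v = VariantSpec(no_top_site=True, no_middle_site=True)
        for s in (0, 1, 2):
            t = ff.assemble_interaction_table(geom, s, v)
            assert t.pair_eps_att[ff.CLASS_TOP_ATT] == 0.0
            assert t.pair_eps_att[ff.CLASS_MID_ATT] == 0.0
        t2 = ff.assemble_interaction_table(geom, 2, VariantSpec(no_top_site=True))
        assert t2.pair_eps_att[ff.CLASS_TOP_ATT] == 0.0
        assert t2.pair_eps_att[ff.CLASS_BOT_ATT] == 0.0

    def test_fold_equilibria_switch(self, geom):
        t0 = ff.assemble_interaction_table(geom, 0)
        t1 = ff.assemble_interaction_table(geom, 1)
        # the kleisin fold dihedral equilibrium moves by ~115 degrees
        dphi = np.abs(np.degrees(t1.dihedral_phi0 - t0.dihedral_phi0))
        dphi = np.minimum(dphi, 360 - dphi)
        assert (dphi > 90).all()

    def test_unknown_state_rejected(self, geom):
        with pytest.raises(ValueError):
            ff.assemble_interaction_table(geom, 3)


class TestGradientIdentity:
    def test_forces_are_exact_gradients(self, perturbed_system):
        """Central-difference check on a random configuration."""
        st = perturbed_system
        f = st.compute_forces()
        rng = np.random.default_rng(1)
        h = 1e-5
        for i in rng.choice(st.n_beads, 30, replace=False):
            for c in range(3):
                st.pos[i, c] += h
                ep = st.potential_energy()
                st.pos[i, c] -= 2 * h
                em = st.potential_energy()
                st.pos[i, c] += h
                numeric = -(ep - em) / (2 * h)
                assert numeric == pytest.approx(
                    f[i, c], rel=1e-6, abs=2e-4), (i, c)

    def test_energy_zero_beyond_cutoffs(self):
        """Beads separated beyond every cutoff: exactly zero pair energy."""
        from smcsim import assemble_system, build_dna
        from smcsim.model_builder import DNAParameters

        dna = build_dna(DNAParameters(beads=20))
        st = assemble_system(dna, None)
        # spread beads far apart on a line, bonds removed
        st.pos[:, 0] = np.arange(20) * 50.0
        st.bond_k[:] = 0.0
        st.ang_kappa[:] = 0.0
        assert st.potential_energy() == 0.0
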