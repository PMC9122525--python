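"""Integrator correctness: equipartition, determinism, conservation."""

import numpy as np
import pytest

from smcsim import (IntegratorSettings, assemble_system, build_dna,
                    build_smcc)
from smcsim import _kernels as K
from smcsim.dynamics import (kinetic_temperatures, langevin_step,
                             rigid_body_spread, rotation_temperature,
                             run_for, run_until)
from smcsim.model_builder import DNAParameters


def _free_body_system(seed=3):
    """50 non-interacting beads + 7 free rigid bodies (couplings off)."""
    dna = build_dna(DNAParameters(beads=50))
    dna.positions += np.array([500.0, 0.0, 0.0])
    st = assemble_system(dna, build_smcc())
    st.bond_k[:] = 0.0
    st.ang_kappa[:] = 0.0
    st.dih_kappa[:] = 0.0
    st.peps_att[:] = 0.0
    st.peps_rep[:] = 0.0
    st.seed_thermostat(seed)
    return st


class TestEquipartition:
    def test_free_bead_and_body_dof_temperatures(self):
        """<KE> per DOF = kT/2 within 2% for bead translation, body
        translation, and rotation about every thermostat-driven axis."""
        st = _free_body_system()
        s = IntegratorSettings(dt=1e-3)
        run_for(st, 20.0, s)
        acc = {"free": [], "trans": [], "rot": []}
        for _ in range(3000):
            run_for(st, 0.5, s)
            t = kinetic_temperatures(st)
            acc["free"].append(t["free_translation"])
            acc["trans"].append(t["body_translation"])
            acc["rot"].append(rotation_temperature(st)[0])
        assert np.mean(acc["free"]) == pytest.approx(1.0, abs=0.02)
        assert np.mean(acc["trans"]) == pytest.approx(1.0, abs=0.02)
        assert np.mean(acc["rot"]) == pytest.approx(1.0, abs=0.02)


class TestDeterminism:
    def test_same_seed_identical_trajectories(self):
        outs = []
        for _ in range(2):
            dna = build_dna(DNAParameters(beads=30))
            st = assemble_system(dna, None)
            st.seed_thermostat(99)
            run_for(st, 2.0, IntegratorSettings())
            outs.append(st.pos.copy())
        assert (outs[0] == outs[1]).all()

    def test_run_until_noop_and_validation(self):
        dna = build_dna(DNAParameters(beads=10))
        st = assemble_system(dna, None)
        st.seed_thermostat(1)
        p0 = st.pos.copy()
        run_until(st, st.time, IntegratorSettings())
        assert (st.pos == p0).all()
        with pytest.raises(ValueError):
            run_until(st, st.time - 1.0, IntegratorSettings())


class TestForces:
    def test_straight_relaxed_dna_force_free(self):
        dna = build_dna(DNAParameters(beads=50))
        st = assemble_system(dna, None)
        assert np.abs(st.compute_forces()).max() < 1e-10

    def test_neighbor_list_matches_brute_force(self, smcc_default):
        """Kernel pair forces equal an all-pairs numpy evaluation."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            dna = build_dna(DNAParameters(beads=40))
            st = assemble_system(dna, smcc_default)
            st.pos[:st.n_dna] = rng.normal(0.0, 12.0, (st.n_dna, 3))
            st.bond_k[:] = 0.0
            st.ang_kappa[:] = 0.0
            st.dih_kappa[:] = 0.0
            f_kernel = st.compute_forces()
            f_ref = np.zeros_like(f_kernel)
            rmin2 = 2.0 ** (1.0 / 3.0)
            for i in range(st.n_dna):
                for j in range(i + 1, st.n_beads):
                    cls = 0 if j < st.n_dna else int(st.bead_class[j])
                    if j < st.n_dna and j - i <= 2:
                        continue
                    d = st.pos[j] - st.pos[i]
                    r2 = d @ d
                    if r2 >= st.prc2[cls]:
                        continue
                    sig2 = st.psig2[cls]
                    eps = (st.peps_rep[cls] if r2 < rmin2 * sig2
                           else st.peps_att[cls])
                    sr6 = (sig2 / r2) ** 3
                    fr = 24 * eps * (2 * sr6 * sr6 - sr6) / r2
                    fmag = abs(fr) * np.sqrt(r2)
                    if fmag > K.FORCE_CAP:
                        fr = np.sign(fr) * K.FORCE_CAP / np.sqrt(r2)
                    f_ref[j] += fr * d
                    f_ref[i] -= fr * d
            assert np.abs(f_kernel - f_ref).max() < 1e-10

    def test_newtons_third_law(self, perturbed_system):
        f = perturbed_system.compute_forces()
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_external_forces_balance(self):
        dna = build_dna()
        st = assemble_system(dna, None)
        st.fext[0] = (-0.1, 0, 0)
        st.fext[-1] = (0.1, 0, 0)
        f = st.compute_forces()
        assert np.abs(f.sum(axis=0)).max() < 1e-9


class TestIntegration:
    def test_energy_conservation_without_thermostat(self):
        """NVE limit: tiny dt, no friction/noise -> drift < 1e-4 relative."""
        dna = build_dna(DNAParameters(beads=30), "thermalized", seed=4)
        st = assemble_system(dna, None)
        rng = np.random.default_rng(0)
        st.vel[:] = rng.normal(0, 5.0, st.vel.shape)
        s = IntegratorSettings(dt=2e-5, damp=1e12)
        e0 = st.potential_energy() + 0.5 * st.mass @ (st.vel ** 2).sum(axis=1)
        run_for(st, 2e-5 * 10000, s)
        e1 = st.potential_energy() + 0.5 * st.mass @ (st.vel ** 2).sum(axis=1)
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_rigid_bodies_stay_rigid(self, small_threaded):
        st = small_threaded.clone()
        st.seed_thermostat(8)
        run_for(st, 5.0, IntegratorSettings(dt=1e-3))
        for b in range(7):
            assert rigid_body_spread(st, b) < 1e-9

    def test_frozen_beads_never_move(self):
        dna = build_dna(DNAParameters(beads=30))
        st = assemble_system(dna, None)
        st.freeze_beads([0, 29])
        st.seed_thermostat(2)
        ends0 = st.pos[[0, 29]].copy()
        run_for(st, 10.0, IntegratorSettings(dt=1e-3))
        assert (st.pos[[0, 29]] == ends0).all()
        assert st.racc_steps > 0

    def test_single_step_advances_clock(self):
        dna = build_dna(DNAParameters(beads=5))
        st = assemble_system(dna, None)
        st.seed_thermostat(0)
        s = IntegratorSettings()
        langevin_step(st, s)
        assert st.time == pytest.approx(s.dt)
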