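"""DNA and SMCC construction: audits, invariants, threading."""

import numpy as np
import pytest

from smcsim import analysis, build_dna, build_smcc
from smcsim import forcefield as ff
from smcsim.model_builder import (ARM_LL, ARM_UL, BRIDGE, KLEISIN, TOP,
                                  DNAParameters, InvalidParameterError,
                                  VariantSpec, fit_persistence_length_tangents,
                                  sample_thermalized_tangents,
                                  thread_extrusion_config,
                                  thread_translocation_config, upper_aperture)
from smcsim.units import AG_TO_INTERNAL_MASS


class TestDna:
    def test_default_contour_length(self):
        dna = build_dna()
        assert dna.params.beads == 301
        assert dna.contour_length == pytest.approx(510.0)
        assert dna.params.length_bp == 1505

    def test_two_bead_single_bond(self):
        dna = build_dna(DNAParameters(beads=2), "straight")
        assert dna.bond_lengths() == pytest.approx([1.7])

    def test_too_few_beads(self):
        with pytest.raises(InvalidParameterError):
            build_dna(DNAParameters(beads=1))

    def test_unknown_conformation(self):
        with pytest.raises(InvalidParameterError):
            build_dna(conformation="wavy")

    def test_thermalized_bond_lengths_exact(self):
        dna = build_dna(conformation="thermalized", seed=3)
        assert dna.bond_lengths() == pytest.approx(1.7)

    def test_thermalized_persistence_length(self):
        """Sequential-sampling ensemble reproduces Lp = 50 nm within 6%."""
        t = sample_thermalized_tangents(DNAParameters(), 10_000, seed=11)
        lp = fit_persistence_length_tangents(t, 1.7)
        assert lp == pytest.approx(50.0, rel=0.06)


class TestSmccAudit:
    @pytest.fixture(scope="class")
    def geom(self):
        return build_smcc()

    def test_bead_counts(self, geom):
        sizes = {b: (geom.body_id == b).sum() for b in range(7)}
        assert sizes[TOP] == 17
        assert sizes[BRIDGE] == 8
        assert sizes[KLEISIN] == 17
        assert (geom.bead_class[geom.top_att] == ff.CLASS_TOP_ATT).all()
        assert len(geom.top_att) == 3
        assert len(geom.mid_att) == 2
        assert len(geom.bot_att) == 3

    def test_total_mass_exact(self, geom):
        assert geom.bead_mass.sum() == pytest.approx(
            0.25 * AG_TO_INTERNAL_MASS, rel=1e-12)

    def test_arm_segment_length(self, geom):
        for body in (ARM_UL, ARM_LL):
            p = geom.positions_by_state[1][geom.body_indices(body)]
            # cell-centred beads: end-to-end spans (n-1)/n of the segment
            n = p.shape[0]
            seg = np.linalg.norm(p[-1] - p[0]) * n / (n - 1)
            assert seg == pytest.approx(25.0, rel=1e-6)

    def test_arm_bead_spacing_impenetrable(self, geom):
        for body in (ARM_UL, ARM_LL):
            p = geom.positions_by_state[0][geom.body_indices(body)]
            d = np.linalg.norm(np.diff(p, axis=0), axis=1)
            assert (d <= 1.5 + 1e-9).all()

    def test_shorter_arms_variant(self):
        geom = build_smcc(VariantSpec(shorter_arms=True))
        p = geom.positions_by_state[1][geom.body_indices(ARM_UL)]
        n = p.shape[0]
        seg = np.linalg.norm(p[-1] - p[0]) * n / (n - 1)
        assert seg == pytest.approx(20.0, rel=1e-6)

    def test_fold_angles_by_state(self):
        geom = build_smcc()
        assert geom.calibration["fold_deg_by_state"] == [45.0, 160.0, 45.0]
        less = build_smcc(VariantSpec(less_folding=True))
        assert less.calibration["fold_deg_by_state"][1] == 130.0

    def test_floppy_elbow_zero_stiffness(self):
        geom = build_smcc(VariantSpec(floppy_elbow=True))
        elbow = [k for lbl, k in zip(geom.angle_labels, geom.angle_kappa)
                 if lbl.startswith("elbow")]
        assert elbow and all(k == 0.0 for k in elbow)

    def test_aperture_open_vs_closed(self):
        """Open state admits a 3.5 nm chain with >= 2 nm clearance
        (arm-arm gap >= 7 nm); the closed state admits none (< 5 nm)."""
        geom = build_smcc()
        assert upper_aperture(geom, 1) >= 7.0
        assert upper_aperture(geom, 0) < 5.0

    def test_invalid_state(self):
        with pytest.raises(InvalidParameterError):
            build_smcc(state_index=5)


class TestThreading:
    def test_translocation_config(self, small_threaded):
        st = small_threaded
        d = np.linalg.norm(st.pos[:st.n_dna]
                           - st.pos[st.bot_att].mean(axis=0), axis=1)
        assert abs(int(np.argmin(d)) - 150) <= 2
        topo = analysis.topology_check(st)
        assert topo.ring_threaded
        assert topo.compartment == "lower"

    def test_translocation_requires_apo(self):
        with pytest.raises(InvalidParameterError):
            thread_translocation_config(build_dna(), build_smcc(state_index=1))

    def test_extrusion_initial_loop(self):
        st = thread_extrusion_config(build_dna(), build_smcc(), 400)
        loop_bp = analysis.measure_loop_beads(st) * 5
        assert abs(loop_bp - 400) <= 5
        assert analysis.topology_check(st).ring_threaded

    def test_extrusion_zero_loop(self):
        # degenerate anchor-adjacent case: the stretched anchor bond
        # distorts the local chain, so allow the +/-1-bead quantization
        # of the position call on top of the one-bead anchor offset
        st = thread_extrusion_config(build_dna(), build_smcc(), 0)
        assert analysis.measure_loop_beads(st) * 5 <= 10

    def test_loop_must_fit(self):
        with pytest.raises(InvalidParameterError):
            thread_extrusion_config(build_dna(), build_smcc(), 2000)

    def test_loop_multiple_of_bead(self):
        with pytest.raises(InvalidParameterError):
            thread_extrusion_config(build_dna(), build_smcc(), 403)
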