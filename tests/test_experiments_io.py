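"""Experiment configs, trajectory/data I/O, fixtures, manifests."""

import numpy as np
import pytest

from smcsim import build_dna, build_smcc, thread_translocation_config
from smcsim import io as io_mod
from smcsim.experiments import (EnsembleSpec, ExperimentConfig,
                                build_fixed_endpoint_state)
from smcsim.model_builder import VariantSpec


class TestConfig:
    def test_minimal_defaults(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("experiment: translocation\ntension_pN: 0.1\n")
        cfg = io_mod.parse_config(p)
        assert cfg.dna_beads == 301
        assert cfg.kind == "translocation"
        assert cfg.ensemble.tension_pn == 0.1

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("experiment: translocation\ntenson_pN: 0.1\n")
        with pytest.raises(io_mod.ConfigError, match="tenson_pN"):
            io_mod.parse_config(p)

    def test_negative_tension_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("experiment: translocation\ntension_pN: -1\n")
        with pytest.raises(io_mod.ConfigError, match="tension"):
            io_mod.parse_config(p)

    def test_roundtrip_identity(self, tmp_path):
        cfg = ExperimentConfig(
            kind="extrusion_fixed_tension",
            ensemble=EnsembleSpec(tension_pn=0.5),
            variant=VariantSpec(shorter_arms=True),
            cycles=7, seed=3, initial_loop_bp=800)
        p = tmp_path / "c.yaml"
        io_mod.write_config(cfg, p)
        assert io_mod.parse_config(p) == cfg

    def test_bad_variant_flag(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("experiment: translocation\nvariant: [no_tp_site]\n")
        with pytest.raises(io_mod.ConfigError, match="no_tp_site"):
            io_mod.parse_config(p)


class TestTrajectories:
    @pytest.mark.parametrize("dialect", ["xyz", "lammps-dump"])
    def test_write_read_roundtrip(self, tmp_path, dialect, small_threaded):
        st = small_threaded
        ext = "xyz" if dialect == "xyz" else "lammpstrj"
        path = tmp_path / f"t.{ext}"
        io_mod.write_trajectory([st], path, dialect)
        frames = io_mod.read_trajectory_positions(path, dialect)
        assert len(frames) == 1
        assert frames[0].shape == st.pos.shape
        assert np.abs(frames[0] - st.pos).max() < 1e-4

    def test_frame_has_all_beads(self, tmp_path, small_threaded):
        path = tmp_path / "t.xyz"
        io_mod.write_trajectory([small_threaded], path, "xyz")
        first = path.read_text().splitlines()[0]
        assert int(first) == small_threaded.n_beads

    def test_dialect_cross_consistency(self, tmp_path, small_threaded):
        p1 = tmp_path / "a.xyz"
        p2 = tmp_path / "a.lammpstrj"
        io_mod.write_trajectory([small_threaded], p1, "xyz")
        io_mod.write_trajectory([small_threaded], p2, "lammps-dump")
        f1 = io_mod.read_trajectory_positions(p1, "xyz")[0]
        f2 = io_mod.read_trajectory_positions(p2, "lammps-dump")[0]
        assert np.abs(f1 - f2).max() < 1e-4


class TestDataFiles:
    def test_configuration_roundtrip(self, tmp_path, small_threaded):
        path = tmp_path / "conf.data"
        io_mod.write_lammps_data(small_threaded, path)
        pos, mol = io_mod.read_lammps_data_positions(path)
        assert np.abs(pos - small_threaded.pos).max() < 1e-6
        assert (mol[:small_threaded.n_dna] == 0).all()
        assert set(mol[small_threaded.n_dna:]) == set(range(1, 8))

    def test_fixture_determinism(self, tmp_path):
        a = io_mod.make_fixture("bare-dna", seed=5, out_dir=tmp_path / "a")
        b = io_mod.make_fixture("bare-dna", seed=5, out_dir=tmp_path / "b")
        assert a.read_bytes() == b.read_bytes()

    def test_bare_dna_fixture_contour(self, tmp_path):
        path = io_mod.make_fixture("bare-dna", seed=0, out_dir=tmp_path)
        pos, _ = io_mod.read_lammps_data_positions(path)
        assert pos.shape[0] == 101
        contour = np.linalg.norm(np.diff(pos, axis=0), axis=1).sum()
        assert contour == pytest.approx(170.0, rel=1e-6)

    def test_threaded_extrusion_fixture(self, tmp_path):
        from smcsim import analysis
        from smcsim import thread_extrusion_config

        st = thread_extrusion_config(build_dna(), build_smcc(), 400)
        assert analysis.topology_check(st).ring_threaded
        path = io_mod.make_fixture("threaded-extrusion", seed=0,
                                   out_dir=tmp_path)
        assert path.exists()


class TestManifest:
    def test_manifest_written_with_checksums(self, tmp_path):
        cfg = ExperimentConfig()
        (tmp_path / "cycle_records.csv").write_text("cycle\n0\n")
        path = io_mod.write_manifest(tmp_path, cfg)
        import yaml

        m = yaml.safe_load(path.read_text())
        assert m["config"]["experiment"] == "translocation"
        assert "cycle_records.csv" in m["outputs"]
        assert m["constants"]["dna_kappa_kBT_rad2"] == pytest.approx(
            29.24, abs=0.1)
        assert "arm_open_angle_deg" in m["smcc_calibration"]


class TestFixedEndpointConstruction:
    def test_terminal_beads_frozen_at_separation(self):
        cfg = ExperimentConfig(
            kind="extrusion_fixed_endpoints",
            ensemble=EnsembleSpec(mode="fixed_endpoints", rel_extension=0.25))
        st = build_fixed_endpoint_state(cfg)
        assert (st.mobility[[0, st.n_dna - 1]] == 0).all()
        outside = (st.n_dna - 1) - 80
        d = np.linalg.norm(st.pos[st.n_dna - 1] - st.pos[0])
        assert d == pytest.approx(0.25 * outside * 1.7, rel=1e-6)
        from smcsim import analysis
        assert analysis.topology_check(st).ring_threaded
        assert analysis.measure_loop_beads(st) in range(76, 85)


class TestCli:
    def test_help_lists_subcommands(self):
        from click.testing import CliRunner
        from smcsim.cli import main

        res = CliRunner().invoke(main, ["--help"])
        assert res.exit_code == 0
        for cmd in ("translocate", "extrude-ft", "extrude-fe", "sweep", "run"):
            assert cmd in res.output

    def test_unknown_variant_flag_rejected(self):
        from click.testing import CliRunner
        from smcsim.cli import main

        res = CliRunner().invoke(main, ["translocate", "--variant", "nope"])
        assert res.exit_code != 0


class TestRecordTables:
    def test_hdf5_roundtrip(self, tmp_path):
        from smcsim.atpase_cycle import CycleRecord

        recs = [CycleRecord(cycle=c, dwell_0=40.0, dwell_1=160.0,
                            dwell_2=40.0, pos_start=150, pos_end=140,
                            step_nm=17.0, step_bp=50.0, substate="1b",
                            segment_nm=34.0) for c in range(3)]
        path = tmp_path / "records.h5"
        io_mod.write_records_hdf5(recs, path)
        frame = io_mod.read_records_hdf5(path)
        assert len(frame) == 3
        assert frame["step_nm"].tolist() == [17.0] * 3
        assert frame["substate"].tolist() == ["1b"] * 3
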