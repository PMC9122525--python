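"""Configuration files, trajectory output, fixtures and run manifests.

Configs are YAML with explicit units in key names (``tension_pN``,
``dt_pLsec``); unknown keys are rejected so typos fail loudly.
Trajectories are written as XYZ or LAMMPS-dump text; initial
configurations as LAMMPS-style data files (atoms, bonds, angles,
dihedrals, rigid-body molecule ids).  Every run directory gets exactly
one YAML manifest echoing all resolved parameters, unit constants,
calibrated values, seeds, and sha256 checksums of the outputs, which is
sufficient to reproduce the run bit-for-bit with the same code version.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__, forcefield as ff
from .experiments import DESK_DT, DESK_SCALE_DOWN, EnsembleSpec, ExperimentConfig
from .model_builder import (DNAParameters, VariantSpec, build_dna, build_smcc,
                            thread_extrusion_config,
                            thread_translocation_config)
from .units import UNITS


class ConfigError(ValueError):
    pass


_VARIANT_KEYS = ("no_top_site", "no_middle_site", "shorter_arms",
                 "less_folding", "floppy_elbow")
_CONFIG_KEYS = {
    "schema_version", "experiment", "tension_pN", "rel_extension",
    "cycles", "initial_loop_bp", "seed", "dna_beads", "variant",
    "scale_down", "dt_pLsec", "burn_in_nLsec", "traj_stride_nLsec",
}


def parse_config(path) -> ExperimentConfig:
    """Read and validate a YAML experiment configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if raw.get("schema_version", 1) != 1:
        raise ConfigError(f"{path}: unsupported schema_version")
    kind = raw.get("experiment", "translocation")
    tension = raw.get("tension_pN", 0.1)
    if tension is not None and tension < 0:
        raise ConfigError(f"{path}: tension_pN: must be non-negative")
    rel_ext = raw.get("rel_extension", 0.25)
    variant_raw = raw.get("variant", {}) or {}
    if isinstance(variant_raw, list):
        variant_raw = {k: True for k in variant_raw}
    bad = set(variant_raw) - set(_VARIANT_KEYS)
    if bad:
        raise ConfigError(f"{path}: variant: unknown flags {sorted(bad)}")
    mode = ("fixed_endpoints" if kind == "extrusion_fixed_endpoints"
            else "fixed_tension")
    try:
        return ExperimentConfig(
            kind=kind,
            ensemble=EnsembleSpec(mode=mode, tension_pn=tension,
                                  rel_extension=rel_ext),
            variant=VariantSpec(**variant_raw),
            cycles=int(raw.get("cycles", 10)),
            initial_loop_bp=int(raw.get("initial_loop_bp", 400)),
            seed=int(raw.get("seed", 0)),
            dna_beads=int(raw.get("dna_beads", 301)),
            dt=float(raw.get("dt_pLsec", DESK_DT * 1e3)) * 1e-3,
            scale_down=float(raw.get("scale_down", DESK_SCALE_DOWN)),
            burn_in=raw.get("burn_in_nLsec"),
            traj_stride=float(raw.get("traj_stride_nLsec", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def serialize_config(config: ExperimentConfig) -> dict:
    """Config as a plain dict, the inverse of :func:`parse_config`."""
    variant = {k: v for k, v in asdict(config.variant).items() if v}
    return {
        "schema_version": 1,
        "experiment": config.kind,
        "tension_pN": config.ensemble.tension_pn,
        "rel_extension": config.ensemble.rel_extension,
        "cycles": config.cycles,
        "initial_loop_bp": config.initial_loop_bp,
        "seed": config.seed,
        "dna_beads": config.dna_beads,
        "variant": variant,
        "scale_down": config.scale_down,
        "dt_pLsec": config.dt * 1e3,
        "burn_in_nLsec": config.burn_in,
        "traj_stride_nLsec": config.traj_stride,
    }


def write_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(serialize_config(config),
                                         sort_keys=True))


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

class TrajectoryWriter:
    """Frame-by-frame text trajectory writer (xyz or lammps-dump)."""

    def __init__(self, path, dialect: str = "xyz"):
        if dialect not in ("xyz", "lammps-dump"):
            raise ValueError(f"unknown trajectory dialect {dialect!r}")
        self.path = Path(path)
        self.dialect = dialect
        self._fh = open(self.path, "w")

    def write_frame(self, state, step: int | None = None) -> None:
        pos = state.pos
        types = np.where(np.arange(pos.shape[0]) < state.n_dna, 1,
                         state.bead_class + 2)
        step = int(state.time * 1e3) if step is None else step
        if self.dialect == "xyz":
            self._fh.write(f"{pos.shape[0]}\n")
            self._fh.write(f"frame time_nLsec={state.time:.6f}\n")
            for t, (x, y, z) in zip(types, pos):
                self._fh.write(f"T{t} {x:.5f} {y:.5f} {z:.5f}\n")
        else:
            lo, hi = pos.min() - 10.0, pos.max() + 10.0
            self._fh.write("ITEM: TIMESTEP\n%d\n" % step)
            self._fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % pos.shape[0])
            self._fh.write("ITEM: BOX BOUNDS ff ff ff\n")
            for _ in range(3):
                self._fh.write(f"{lo:.5f} {hi:.5f}\n")
            self._fh.write("ITEM: ATOMS id type x y z\n")
            for i, (t, (x, y, z)) in enumerate(zip(types, pos), start=1):
                self._fh.write(f"{i} {t} {x:.5f} {y:.5f} {z:.5f}\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_trajectory(states, path, dialect: str = "xyz") -> Path:
    """Write a sequence of states as a trajectory file."""
    with TrajectoryWriter(path, dialect) as tw:
        for k, st in enumerate(states):
            tw.write_frame(st, step=k)
    return Path(path)


def read_trajectory_positions(path, dialect: str = "xyz") -> list[np.ndarray]:
    """Reload trajectory coordinates (via MDAnalysis)."""
    import warnings

    import MDAnalysis as mda

    fmt = "XYZ" if dialect == "xyz" else "LAMMPSDUMP"
    offset = 0.0
    if dialect == "lammps-dump":
        # MDAnalysis shifts dump coordinates to a zero-origin box; undo
        # using the box lower bound we wrote
        lines = Path(path).read_text().splitlines()
        k = lines.index("ITEM: BOX BOUNDS ff ff ff")
        offset = np.array([float(lines[k + 1 + i].split()[0])
                           for i in range(3)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)
        return [u.atoms.positions.astype(float) + offset
                for _ in u.trajectory]


# --------------------------------------------------------------------------
# LAMMPS-style data files (initial configurations)
# --------------------------------------------------------------------------

def write_lammps_data(state, path) -> Path:
    """Save a configuration as a LAMMPS-style molecular data file.

    Molecule id 0 marks DNA; rigid bodies are molecules 1..7.
    """
    pos = state.pos
    n = pos.shape[0]
    lines = ["# smcsim configuration", ""]
    lines.append(f"{n} atoms")
    lines.append(f"{state.bond_ij.shape[0]} bonds")
    lines.append(f"{state.ang_ijk.shape[0]} angles")
    lines.append(f"{state.dih_ijkl.shape[0]} dihedrals")
    lines.append("")
    lo, hi = pos.min() - 10.0, pos.max() + 10.0
    for ax in "xyz":
        lines.append(f"{lo:.6f} {hi:.6f} {ax}lo {ax}hi")
    lines.append("")
    lines.append("Atoms # molecular")
    lines.append("")
    for i in range(n):
        mol = int(state.body_of[i]) + 1 if state.body_of[i] >= 0 else 0
        typ = 1 if i < state.n_dna else int(state.bead_class[i]) + 2
        x, y, z = pos[i]
        lines.append(f"{i + 1} {mol} {typ} {x:.8f} {y:.8f} {z:.8f}")
    lines.append("")
    lines.append("Bonds")
    lines.append("")
    for b, (i, j) in enumerate(state.bond_ij, start=1):
        kind = int(state.bond_kind[b - 1]) + 1
        lines.append(f"{b} {kind} {i + 1} {j + 1}")
    lines.append("")
    lines.append("Angles")
    lines.append("")
    for a, (i, j, k) in enumerate(state.ang_ijk, start=1):
        lines.append(f"{a} 1 {i + 1} {j + 1} {k + 1}")
    lines.append("")
    lines.append("Dihedrals")
    lines.append("")
    for d, (i, j, k, l) in enumerate(state.dih_ijkl, start=1):
        lines.append(f"{d} 1 {i + 1} {j + 1} {k + 1} {l + 1}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_lammps_data_positions(path) -> tuple[np.ndarray, np.ndarray]:
    """Positions and molecule ids back from a data file written above."""
    txt = Path(path).read_text().splitlines()
    n = int(txt[2].split()[0])
    start = txt.index("Atoms # molecular") + 2
    pos = np.empty((n, 3))
    mol = np.empty(n, dtype=np.int64)
    for line in txt[start:start + n]:
        parts = line.split()
        idx = int(parts[0]) - 1
        mol[idx] = int(parts[1])
        pos[idx] = [float(parts[3]), float(parts[4]), float(parts[5])]
    return pos, mol


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0, out_dir=".",
                 dna_beads: int | None = None) -> Path:
    """Build a small starting state and save it as a data file.

    ``kind``: ``threaded-translocation`` | ``threaded-extrusion`` |
    ``bare-dna``.  ``dna_beads`` defaults to 301 for threaded kinds and
    101 (a reduced test molecule) for bare DNA.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "bare-dna":
        beads = dna_beads or 101
        dna = build_dna(DNAParameters(beads=beads), "thermalized", seed)
        from .system import assemble_system
        state = assemble_system(dna, None)
    elif kind in ("threaded-translocation", "threaded-extrusion"):
        beads = dna_beads or 301
        dna = build_dna(DNAParameters(beads=beads))
        smcc = build_smcc()
        if kind == "threaded-translocation":
            state = thread_translocation_config(dna, smcc)
        else:
            state = thread_extrusion_config(dna, smcc, 400)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    path = out_dir / f"{kind}-{seed}.data"
    write_lammps_data(state, path)
    return path


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: ExperimentConfig,
                   extra: dict | None = None) -> Path:
    """Write the run manifest (one per run directory)."""
    out_dir = Path(out_dir)
    smcc = build_smcc(config.variant)
    manifest = {
        "code_version": __version__,
        "config": serialize_config(config),
        "units": UNITS.as_dict(),
        "constants": {
            "eps_top_kBT": ff.EPS_TOP,
            "eps_mid_kBT": ff.EPS_MID,
            "eps_bot_kBT": ff.EPS_BOT,
            "dna_bond_nm": ff.BOND_REST,
            "dna_kappa_kBT_rad2": float(ff.calibrate_dna_bending_kappa()),
            "persistence_length_nm": ff.PERSISTENCE_LENGTH,
            "dwell_means_uLsec": [0.4, 1.6, 0.4],
            "transition_ramp_nLsec_unscaled": 50.0,
        },
        "smcc_calibration": {k: (list(v) if isinstance(v, list) else v)
                             for k, v in smcc.calibration.items()},
        "seeds": {"master": config.seed},
        "outputs": {},
    }
    if extra:
        manifest.update(extra)
    for f in sorted(out_dir.glob("*")):
        if f.name != "manifest.yaml" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


# --------------------------------------------------------------------------
# cycle-record tables
# --------------------------------------------------------------------------

#: cycle-record table schema version (columns of the CSV/HDF5 outputs)
RECORD_SCHEMA_VERSION = 1


def write_records_hdf5(records, path) -> Path:
    """Save a cycle-record stream as an HDF5 table (one row per cycle)."""
    import h5py
    import pandas as pd

    frame = pd.DataFrame([r.as_dict() for r in records])
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = RECORD_SCHEMA_VERSION
        g = h5.create_group("cycles")
        for col in frame.columns:
            data = frame[col]
            if data.dtype == object:
                g.create_dataset(
                    col, data=np.array(
                        ["" if v is None else str(v) for v in data],
                        dtype=h5py.string_dtype()))
            else:
                g.create_dataset(col, data=data.to_numpy(dtype=float))
    return Path(path)


def read_records_hdf5(path):
    """Reload a cycle-record table written by :func:`write_records_hdf5`."""
    import h5py
    import pandas as pd

    with h5py.File(path, "r") as h5:
        g = h5["cycles"]
        cols = {}
        for name in g:
            arr = g[name][()]
            if arr.dtype.kind in ("S", "O"):
                cols[name] = [v.decode() if isinstance(v, bytes) else v
                              for v in arr]
            else:
                cols[name] = arr
        return pd.DataFrame(cols)
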