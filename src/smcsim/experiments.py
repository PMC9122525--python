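"""Experiment drivers: translocation and the two loop-extrusion ensembles.

``fixed_tension`` applies equal and opposite stretching forces to the
two DNA end beads; ``fixed_endpoints`` immobilizes the terminal beads at
a separation set by the requested relative extension of the DNA outside
the extruded loop, and estimates the DNA tension each cycle from the
mean restraint force on the frozen ends.

Production profile: these drivers default to a timestep of 1 pLsec and
a scale-down factor of 10 (dwell times and friction divided by ten),
which preserves the diffusive transport per ATPase cycle while keeping
a multi-cycle run tractable on one CPU core; manifests record both
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis, model_builder
from .atpase_cycle import CycleRates, CycleRecord, run_cycle
from .dynamics import IntegratorSettings, run_for
from .model_builder import (DNAParameters, VariantSpec, build_dna, build_smcc,
                            thread_extrusion_config,
                            thread_translocation_config, _arc_through)
from .system import SystemState
from .units import pn_to_internal

#: desk-scale production profile (see module docstring)
DESK_DT = 1.0e-3          # nLsec (= 1 pLsec)
DESK_SCALE_DOWN = 10.0


class TopologyLost(RuntimeError):
    """The SMCC lost its topological grip on the DNA.

    Carries the cycle records accumulated before the detachment.
    """

    def __init__(self, message, records=None):
        super().__init__(message)
        self.records = records or []


@dataclass(frozen=True)
class EnsembleSpec:
    """How DNA tension is imposed."""

    mode: str = "fixed_tension"            # or "fixed_endpoints"
    tension_pn: float = 0.1
    rel_extension: float = 0.25

    def __post_init__(self):
        if self.mode not in ("fixed_tension", "fixed_endpoints"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")
        if self.mode == "fixed_tension" and self.tension_pn < 0:
            raise ValueError("tension must be non-negative")
        if not 0.0 < self.rel_extension < 1.0:
            raise ValueError("relative extension must be in (0, 1)")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one run; determines it given the code version."""

    kind: str = "translocation"
    ensemble: EnsembleSpec = EnsembleSpec()
    variant: VariantSpec = VariantSpec()
    cycles: int = 10
    initial_loop_bp: int = 400
    seed: int = 0
    dna_beads: int = 301
    dt: float = DESK_DT
    scale_down: float = DESK_SCALE_DOWN
    burn_in: float | None = None           # nLsec; default: one apo dwell
    traj_stride: float = 0.0               # nLsec between frames; 0 = off
    mass_scale: float = 1.0                # bead-mass multiplier (kinetics
    # are mass-insensitive; exposed for the invariance property)

    def __post_init__(self):
        if self.kind not in ("translocation", "extrusion_fixed_tension",
                             "extrusion_fixed_endpoints"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.cycles < 1:
            raise ValueError("cycle count must be positive")

    def settings(self) -> IntegratorSettings:
        return IntegratorSettings(dt=self.dt, scale_down=self.scale_down,
                                  seed=self.seed)


def _seeds(seed: int) -> tuple[int, int]:
    """(thermostat seed, dwell-sampling seed) substreams below 2**31."""
    ss = np.random.SeedSequence(seed)
    a, b = ss.generate_state(2, dtype=np.uint32)
    return int(a >> 1), int(b >> 1)


def _apply_tension(state: SystemState, tension_pn: float) -> None:
    f = pn_to_internal(tension_pn)
    state.fext[0] = (-f, 0.0, 0.0)
    state.fext[state.n_dna - 1] = (f, 0.0, 0.0)


def _apply_mass_scale(state: SystemState, scale: float) -> None:
    if scale != 1.0:
        state.mass *= scale
        state.sync_bodies_from_beads()


def _burn_in(state, config, rates, settings) -> None:
    t = config.burn_in
    if t is None:
        t = rates.tau_01 / settings.scale_down
    run_for(state, t, settings)


def _cycle_loop(state, config, rates, settings, observers=None
                ) -> list[CycleRecord]:
    rng = np.random.default_rng(_seeds(config.seed)[1])
    records = []
    bad_topo = 0
    for c in range(config.cycles):
        state, rec = run_cycle(state, rates, settings, rng, c)
        records.append(rec)
        bad_topo = bad_topo + 1 if not rec.topology_ok else 0
        if bad_topo >= 2:
            raise TopologyLost(
                f"ring threading lost at cycle {c}: the SMCC detached",
                records)
        if observers:
            for ob in observers:
                ob(state, rec)
    return records


def run_translocation(config: ExperimentConfig,
                      rates: CycleRates = CycleRates(),
                      observers=None) -> list[CycleRecord]:
    """Translocation along DNA at fixed tension.

    Cycles are run *independently* from the same threaded initial
    condition (fresh thermal history each cycle), so the motor always
    starts near the middle of the track: per-cycle step statistics are
    built by stacking independent single cycles rather than one long
    processive run, which on a finite track would let the motor reach
    the DNA end.
    """
    if config.kind != "translocation":
        raise ValueError("config.kind must be 'translocation'")
    if config.ensemble.mode != "fixed_tension":
        raise ValueError("translocation runs use the fixed-tension ensemble")
    settings = config.settings()
    dna = build_dna(DNAParameters(beads=config.dna_beads))
    smcc = build_smcc(config.variant, state_index=0)
    template = thread_translocation_config(dna, smcc)
    _apply_tension(template, config.ensemble.tension_pn)
    _apply_mass_scale(template, config.mass_scale)
    ss = np.random.SeedSequence(config.seed)
    cycle_seeds = ss.generate_state(2 * config.cycles, dtype=np.uint32) >> 1
    records = []
    for c in range(config.cycles):
        state = template.clone()
        state.seed_thermostat(int(cycle_seeds[2 * c]))
        rng = np.random.default_rng(int(cycle_seeds[2 * c + 1]))
        _burn_in(state, config, rates, settings)
        state, rec = run_cycle(state, rates, settings, rng, c)
        records.append(rec)
        if observers:
            for ob in observers:
                ob(state, rec)
    return records


def run_extrusion_fixed_tension(config: ExperimentConfig,
                                rates: CycleRates = CycleRates(),
                                observers=None) -> list[CycleRecord]:
    """Loop extrusion with a safety belt at fixed DNA tension."""
    if config.kind != "extrusion_fixed_tension":
        raise ValueError("config.kind must be 'extrusion_fixed_tension'")
    settings = config.settings()
    dna = build_dna(DNAParameters(beads=config.dna_beads))
    smcc = build_smcc(config.variant, state_index=0)
    state = thread_extrusion_config(dna, smcc, config.initial_loop_bp)
    state.seed_thermostat(_seeds(config.seed)[0])
    _apply_tension(state, config.ensemble.tension_pn)
    _burn_in(state, config, rates, settings)
    return _cycle_loop(state, config, rates, settings, observers)


def build_fixed_endpoint_state(config: ExperimentConfig) -> SystemState:
    """Threaded safety-belt state with terminal beads frozen.

    The DNA outside the initial loop is laid out as two lateral arcs
    whose end points are pinned at a straight-line separation of
    ``rel_extension`` times the outside contour length.
    """
    dna = build_dna(DNAParameters(beads=config.dna_beads))
    smcc = build_smcc(config.variant, state_index=0)
    state = thread_extrusion_config(dna, smcc, config.initial_loop_bp,
                                    relax=False)
    n = state.n_dna
    b = dna.params.bond_length
    loop_beads = config.initial_loop_bp // dna.params.bp_per_bead
    i_pos = (n - 1) // 2 - loop_beads // 2
    i_anchor = i_pos + max(loop_beads, 1)
    outside = (n - 1) - (i_anchor - i_pos)
    d = config.ensemble.rel_extension * outside * b

    p_anchor = state.pos[i_anchor]
    p_exit = state.pos[i_pos]
    mid = 0.5 * (p_anchor + p_exit)
    end_a = mid + np.array([-0.5 * d, 0.0, 0.0])
    end_b = mid + np.array([+0.5 * d, 0.0, 0.0])
    xhat = np.array([1.0, 0.0, 0.0])
    # side A (ahead of the motor) leaves the pocket along the threading
    # axis (-x) before detouring to the fixed end
    stub = 10
    idx = np.arange(i_pos - stub, i_pos)
    state.pos[idx] = p_exit[None, :] + ((idx - i_pos) * b)[:, None] * xhat
    s_end = p_exit - stub * b * xhat
    n_a = i_pos - stub
    if n_a > 0:
        arc = _arc_through(s_end, end_a, n_a * b,
                           np.array([0.0, 1.0, 0.0]), n_a - 1)
        state.pos[i_pos - stub - 1:0:-1] = arc[:n_a - 1]
        state.pos[0] = end_a
    # side B: beads beyond the anchor out to the other fixed end
    n_b = (n - 1) - i_anchor
    if n_b > 0:
        arc = _arc_through(p_anchor, end_b, n_b * b,
                           np.array([0.0, -1.0, 0.0]), n_b - 1)
        state.pos[i_anchor + 1:n - 1] = arc[:n_b - 1]
        state.pos[n - 1] = end_b
    state.freeze_beads([0, n - 1])
    from .system import relax
    relax(state)
    return state


def run_extrusion_fixed_endpoints(config: ExperimentConfig,
                                  rates: CycleRates = CycleRates(),
                                  observers=None) -> list[CycleRecord]:
    """Loop extrusion with the DNA termini immobilized.

    Per-cycle tension is estimated from the time-averaged restraint
    force on the frozen terminal beads projected on the end-to-end axis.
    """
    if config.kind != "extrusion_fixed_endpoints":
        raise ValueError("config.kind must be 'extrusion_fixed_endpoints'")
    settings = config.settings()
    state = build_fixed_endpoint_state(config)
    state.seed_thermostat(_seeds(config.seed)[0])
    rates = rates
    _burn_in(state, config, rates, settings)
    return _cycle_loop(state, config, rates, settings, observers)


RUNNERS = {
    "translocation": run_translocation,
    "extrusion_fixed_tension": run_extrusion_fixed_tension,
    "extrusion_fixed_endpoints": run_extrusion_fixed_endpoints,
}


def run_experiment(config: ExperimentConfig, **kw) -> list[CycleRecord]:
    return RUNNERS[config.kind](config, **kw)


def summarize_steps(records) -> dict:
    """Mean step +/- SE (nm) over non-futile cycles."""
    steps = np.array([r.step_nm for r in records if r.step_nm is not None])
    if steps.size == 0:
        return {"n": 0, "mean_step_nm": np.nan, "se_step_nm": np.nan}
    return {
        "n": int(steps.size),
        "mean_step_nm": float(steps.mean()),
        "se_step_nm": float(steps.std(ddof=1) / np.sqrt(steps.size))
        if steps.size > 1 else np.nan,
        "max_step_nm": float(steps.max()),
        "min_step_nm": float(steps.min()),
    }


def run_variant_sweep(base: ExperimentConfig,
                      variants: list[VariantSpec],
                      tensions_pn: list[float] | None = None) -> pd.DataFrame:
    """Re-run the base experiment for each variant (x tension grid)."""
    tensions = tensions_pn or [base.ensemble.tension_pn]
    rows = []
    for variant in variants:
        for f in tensions:
            cfg = replace(base, variant=variant,
                          ensemble=replace(base.ensemble, tension_pn=f))
            recs = run_experiment(cfg)
            s = summarize_steps(recs)
            rows.append({"variant": variant.label(), "tension_pn": f, **s})
    return pd.DataFrame(rows)
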