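"""The stochastic apo -> ATP -> ADP -> apo conformational cycle.

State dwell times are exponentially distributed with means
``tau_01 = 0.4``, ``tau_12 = 1.6`` and ``tau_20 = 0.4`` microLsec
(mean cycle 2.4 microLsec); ATP hydrolysis (the exit from state 1) is
rate limiting.  Transitions switch the equilibrium angles of the
inter-body couplings and toggle binding-site attractions and the
ATPase-bridge excluded volume; they are *never* contingent on DNA being
bound anywhere, so futile cycles occur naturally.

A cycle, as recorded here, runs from one apo checkpoint to the next:
the motor position is read at the end of each apo dwell, immediately
before ATP binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analysis
from . import forcefield as ff
from .dynamics import IntegratorSettings, run_for
from .system import SystemState
from .units import internal_to_pn

#: durations (nLsec, before scale-down) over which a conformational
#: transition's equilibrium angles, binding-site strengths and the
#: appearing/disappearing bridge are ramped, with the friction boost
#: applied during the ramp: each conformational change is driven as a
#: strongly damped quasi-static sweep rather than an impulsive jump.
TRANSITION_RAMP = {1: (50.0, 10.0), 2: (50.0, 10.0), 0: (50.0, 10.0)}
#: sign convention: with the kleisin fold towards +x, the motor steps
#: towards decreasing bead index; steps are reported positive forward
TRANSLOCATION_SIGN = -1


class StateMachineViolation(RuntimeError):
    pass


@dataclass(frozen=True)
class CycleRates:
    """Mean dwell times of the three states, in nLsec."""

    tau_01: float = 400.0    # apo, 0.4 microLsec
    tau_12: float = 1600.0   # ATP-bound, 1.6 microLsec
    tau_20: float = 400.0    # ADP-bound, 0.4 microLsec

    @property
    def mean_cycle(self) -> float:
        return self.tau_01 + self.tau_12 + self.tau_20

    def tau(self, state_index: int) -> float:
        return (self.tau_01, self.tau_12, self.tau_20)[state_index]


@dataclass
class CycleRecord:
    """Per-cycle observables."""

    cycle: int
    dwell_0: float
    dwell_1: float
    dwell_2: float
    pos_start: int | None
    pos_end: int | None
    step_nm: float | None
    step_bp: float | None
    substate: str | None
    segment_nm: float | None
    loop_bp: float | None = None
    loop_nm: float | None = None
    tension_pn: float | None = None
    futile: bool = False
    topology_ok: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def sample_dwell(state_index: int, rates: CycleRates, rng) -> float:
    """Exponential dwell time (nLsec) for a state."""
    if state_index not in (0, 1, 2):
        raise ValueError(f"unknown SMCC state {state_index!r}")
    return float(rng.exponential(rates.tau(state_index)))


def apply_transition(state: SystemState, to_state: int) -> SystemState:
    """Switch the SMCC to the next conformational state.

    Only forward transitions 0->1->2->0 are allowed.  The interaction
    table is reassembled, equilibrium angles switch instantly, and the
    appearing bridge (0->1) starts at zero excluded volume so it can be
    ramped in without clashing with overlapping DNA.
    """
    if to_state != (state.smcc_state_index + 1) % 3:
        raise StateMachineViolation(
            f"transition {state.smcc_state_index}->{to_state} out of sequence")
    table = ff.assemble_interaction_table(state.smcc, to_state,
                                          state.smcc.variant)
    if to_state == 1:
        table.bridge_scale = 0.0
    state.apply_table(table)
    return state


def _ramped_transition(state: SystemState, to_state: int,
                       settings: IntegratorSettings) -> float:
    """Transition with equilibria interpolated over a short window.

    Angle/dihedral equilibria are interpolated linearly (dihedrals along
    the shortest angular path) and the bridge excluded volume fades in
    or out with the same schedule; friction is temporarily raised so the
    power stroke proceeds as an overdamped sweep rather than an
    impulsive jump.  Returns the simulation time consumed.
    """
    from dataclasses import replace

    nda = state.n_dna_angles
    th_old = state.ang_th0[nda:].copy()
    ph_old = state.dih_phi0.copy()
    rep_old = state.peps_rep.copy()
    att_old = state.peps_att.copy()
    apply_transition(state, to_state)
    table_new = state.table
    table_new.bridge_scale = 1.0
    state.apply_table(table_new)
    th_new = state.ang_th0[nda:].copy()
    dph = np.remainder(state.dih_phi0 - ph_old + np.pi, 2.0 * np.pi) - np.pi
    rep_new = state.peps_rep.copy()
    att_new = state.peps_att.copy()

    ramp_time, boost = TRANSITION_RAMP[to_state]
    total = ramp_time / settings.scale_down
    damped = replace(settings, scale_down=settings.scale_down / boost)
    n_incr = 10
    for k in range(1, n_incr + 1):
        a = k / n_incr
        state.ang_th0[nda:] = (1.0 - a) * th_old + a * th_new
        state.dih_phi0[:] = ph_old + a * dph
        state.peps_rep[:] = (1.0 - a) * rep_old + a * rep_new
        state.peps_att[:] = (1.0 - a) * att_old + a * att_new
        run_for(state, total / n_incr, damped)
    state.apply_table(table_new)
    return total


def run_cycle(state: SystemState, rates: CycleRates,
              settings: IntegratorSettings, rng,
              cycle_index: int = 0) -> tuple[SystemState, CycleRecord]:
    """Run one full ATPase cycle from an apo checkpoint.

    The state must be in the apo conformation.  Dwells for states 1, 2
    and the trailing apo dwell are sampled, scaled by
    ``settings.scale_down``, and simulated in order; the captured
    segment is sampled at the last instant of state 1 and the position
    at the end of the trailing apo dwell.
    """
    if state.smcc_state_index != 0:
        raise StateMachineViolation("run_cycle must start in the apo state")
    s = settings.scale_down
    d1 = sample_dwell(1, rates, rng) / s
    d2 = sample_dwell(2, rates, rng) / s
    d0 = sample_dwell(0, rates, rng) / s

    has_dna = state.n_dna > 0
    pos_start = analysis.smcc_position_on_dna(state) if has_dna else None
    state.racc[:] = 0.0
    state.racc_steps = 0

    used = _ramped_transition(state, 1, settings)
    run_for(state, max(d1 - used, 0.0), settings)
    substate = segment = None
    if has_dna:
        substate, segment = analysis.detect_captured_segment(state)

    used = _ramped_transition(state, 2, settings)
    run_for(state, max(d2 - used, 0.0), settings)

    used = _ramped_transition(state, 0, settings)
    run_for(state, max(d0 - used, 0.0), settings)

    pos_end = analysis.smcc_position_on_dna(state) if has_dna else None
    bond = state.dna.params.bond_length if has_dna else 0.0
    bpb = state.dna.params.bp_per_bead if has_dna else 0
    step_nm = step_bp = None
    if has_dna:
        step_nm = TRANSLOCATION_SIGN * (pos_end - pos_start) * bond
        step_bp = TRANSLOCATION_SIGN * (pos_end - pos_start) * bpb

    loop_bp = loop_nm = None
    if has_dna and state.dna_anchor_bead >= 0:
        lb = analysis.measure_loop_beads(state)
        loop_bp, loop_nm = lb * bpb, lb * bond

    tension = None
    frozen = np.nonzero(state.mobility == 0)[0]
    if frozen.size == 2 and state.racc_steps > 0:
        mean_f = state.racc[frozen] / state.racc_steps
        axis = state.pos[frozen[1]] - state.pos[frozen[0]]
        axis /= max(np.linalg.norm(axis), 1e-12)
        # restraint force balances the pull of the chain on each end
        t0 = abs(mean_f[0] @ axis)
        t1 = abs(mean_f[1] @ axis)
        tension = internal_to_pn(0.5 * (t0 + t1))

    topo_ok = True
    if has_dna:
        try:
            topo_ok = analysis.topology_check(state).ring_threaded
        except analysis.InvalidStateError:
            topo_ok = False

    rec = CycleRecord(
        cycle=cycle_index, dwell_0=d0, dwell_1=d1, dwell_2=d2,
        pos_start=pos_start, pos_end=pos_end,
        step_nm=step_nm, step_bp=step_bp,
        substate=substate, segment_nm=segment,
        loop_bp=loop_bp, loop_nm=loop_nm,
        tension_pn=tension, futile=not has_dna, topology_ok=topo_ok)
    return state, rec


def records_to_frame(records) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame([r.as_dict() for r in records])
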