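"""Langevin dynamics driver: velocity-Verlet with an implicit solvent.

Free DNA beads follow bead Langevin dynamics; the SMCC's rigid bodies
are propagated from aggregated bead forces and torques with a
quaternion orientation update.  The thermostat acts on every bead with
friction ``gamma_i = m_i / damp`` and matching random kicks, so
fluctuation-dissipation holds per degree of freedom for both free beads
and rigid bodies.

The ``scale_down`` factor of :class:`IntegratorSettings` uniformly
divides both the state-machine dwell times and the friction
coefficients.  Because every relevant transport process here is
diffusive, dividing time scales and multiplying diffusion constants by
the same factor leaves the per-cycle statistics invariant while
shortening runs proportionally; acceptance-scale runs record the factor
used in their manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _kernels as K
from .system import NEIGHBOR_SKIN, IntegrationFailure, SystemState

#: default timestep, nLsec (= 0.2 pLsec)
DEFAULT_DT = 2.0e-4
#: thermostat relaxation time, nLsec
DEFAULT_DAMP = 0.5


@dataclass
class IntegratorSettings:
    """Integration parameters (times in nLsec, kT = 1)."""

    dt: float = DEFAULT_DT
    temperature_kT: float = 1.0
    damp: float = DEFAULT_DAMP
    seed: int = 0
    scale_down: float = 1.0
    chunk_steps: int = 4000

    def gamma(self, mass: np.ndarray) -> np.ndarray:
        return mass / (self.damp * self.scale_down)


@dataclass
class Observer:
    """Callback sampled at a fixed simulation-time stride."""

    interval: float
    callback: Callable[[SystemState], None]
    next_time: float = field(default=None)


def compute_forces(state: SystemState, table=None):
    """Per-bead conservative forces plus per-body force and torque.

    If ``table`` is given it must match the state's current SMCC state.
    """
    if table is not None:
        if table.state_index != state.smcc_state_index:
            raise ValueError("interaction table does not match the "
                             "current SMCC state")
        state.apply_table(table)
    f = state.compute_forces()
    nb = state.n_bodies
    bf = np.zeros((max(nb, 1), 3))
    bt = np.zeros((max(nb, 1), 3))
    if nb:
        K._aggregate_bodies(state.pos, f, state.body_of, nb, state.bcom,
                            bf, bt)
    return f, bf[:nb], bt[:nb]


def _run_kernel(state: SystemState, settings: IntegratorSettings,
                nsteps: int) -> None:
    gamma = settings.gamma(state.mass)
    cnoise = np.sqrt(2.0 * gamma * settings.temperature_kT / settings.dt)
    while True:
        status = K.run_steps(
            nsteps, settings.dt, settings.temperature_kT,
            state.pos, state.vel, state.mass, gamma, cnoise, state.mobility,
            state.body_of, state.n_bodies, state.bmass, state.binert,
            state.bcom, state.bquat, state.bvel, state.bang, state.Xb,
            state.bond_ij, state.bond_kind, state.bond_k, state.bond_r0,
            state.bond_rmax, state.ang_ijk, state.ang_kappa, state.ang_th0,
            state.dih_ijkl, state.dih_kappa, state.dih_phi0,
            state.bead_class, state.n_dna, state.peps_rep, state.peps_att,
            state.psig2, state.prc2, state.pshift, state.rlist2, state.excl_a,
            state.excl_b, state.nl_i, state.nl_j, state.n_pairs,
            state.ref_pos, NEIGHBOR_SKIN, state.fext, state.racc,
            state.rng_state)
        if status == -1:
            state._grow_nl()
            state.rebuild_neighbor_list()
            continue
        if status == 1:
            raise IntegrationFailure(
                "non-finite coordinate encountered during integration")
        break
    state.racc_steps += nsteps
    state.time += nsteps * settings.dt


def langevin_step(state: SystemState, settings: IntegratorSettings,
                  table=None) -> SystemState:
    """Advance a single timestep (mostly useful for tests)."""
    if table is not None:
        state.apply_table(table)
    _run_kernel(state, settings, 1)
    return state


def run_until(state: SystemState, t_end: float,
              settings: IntegratorSettings,
              observers: list[Observer] | None = None) -> SystemState:
    """Advance until the simulation clock reaches ``t_end`` (nLsec)."""
    if t_end < state.time - 1e-12:
        raise ValueError("t_end precedes the current simulation clock")
    observers = observers or []
    for ob in observers:
        if ob.next_time is None:
            ob.next_time = state.time + ob.interval
    while state.time < t_end - 1e-12:
        t_next = min([t_end] + [ob.next_time for ob in observers])
        nsteps = max(1, int(round((t_next - state.time) / settings.dt)))
        while nsteps > 0:
            take = min(nsteps, settings.chunk_steps)
            _run_kernel(state, settings, take)
            nsteps -= take
        for ob in observers:
            if state.time >= ob.next_time - 1e-9:
                ob.callback(state)
                ob.next_time += ob.interval
    return state


def run_for(state: SystemState, duration: float,
            settings: IntegratorSettings,
            observers: list[Observer] | None = None) -> SystemState:
    return run_until(state, state.time + duration, settings, observers)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def kinetic_temperatures(state: SystemState) -> dict:
    """kT estimates per DOF class (free translation, body trans/rot)."""
    out = {}
    free = state.mobility == 1
    if free.any():
        ke = 0.5 * state.mass[free] @ (state.vel[free] ** 2).sum(axis=1)
        out["free_translation"] = 2.0 * ke / (3.0 * free.sum())
    nb = state.n_bodies
    if nb:
        ket = 0.5 * state.bmass[:nb] @ (state.bvel[:nb] ** 2).sum(axis=1)
        out["body_translation"] = 2.0 * ket / (3.0 * nb)
        ker = 0.0
        for b in range(nb):
            R = np.empty((3, 3))
            K._quat_to_rot(state.bquat[b], R)
            L_body = R.T @ state.bang[b]
            ker += 0.5 * (L_body ** 2 / state.binert[b]).sum()
        out["body_rotation"] = 2.0 * ker / (3.0 * nb)
    return out


def rotation_temperature(state: SystemState, bodies=None) -> tuple[float, int]:
    """Pooled kT estimate over *driven* rotational DOFs.

    A principal axis of a collinear body carries no thermostat torque
    (every bead sits on the axis), so its angular momentum stays at its
    initial value; such axes are excluded by an inertia threshold.
    Returns (mean kT per driven DOF, number of driven DOFs).
    """
    import numpy as _np

    bodies = range(state.n_bodies) if bodies is None else bodies
    sphere = 0.4 * 0.75 ** 2
    total, ndof = 0.0, 0
    for b in bodies:
        R = _np.empty((3, 3))
        K._quat_to_rot(state.bquat[b], R)
        L_body = R.T @ state.bang[b]
        driven = state.binert[b] > 1.5 * sphere * state.bmass[b]
        total += (L_body[driven] ** 2 / state.binert[b][driven]).sum()
        ndof += int(driven.sum())
    return total / max(ndof, 1), ndof


def rigid_body_spread(state: SystemState, body: int) -> float:
    """Max relative drift of intra-body bead distances vs the body frame."""
    idx = np.nonzero(state.body_of == body)[0]
    d_now = np.linalg.norm(state.pos[idx[0]] - state.pos[idx[-1]])
    d_ref = np.linalg.norm(state.Xb[idx[0]] - state.Xb[idx[-1]])
    return abs(d_now - d_ref) / d_ref
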