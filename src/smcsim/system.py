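"""Assembly of DNA + SMCC into a single dynamical system state.

:class:`SystemState` owns every array the compiled kernels operate on:
bead positions/velocities, rigid-body centres/quaternions/momenta, the
bonded-term tables (with mutable equilibrium angles, switched by the
conformational state machine) and the DNA-vs-class pair matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from . import forcefield as ff
from .model_builder import DNAPolymer, SMCCGeometry
from .units import ag_to_mass

NEIGHBOR_SKIN = 3.0


class IntegrationFailure(RuntimeError):
    pass


def _rot_to_quat(R: np.ndarray) -> np.ndarray:
    t = np.trace(R)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2.0
        q = np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                      (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1e-12, 1.0 + R[i, i] - R[j, j] - R[k, k])) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    return q / np.linalg.norm(q)


@dataclass
class SystemState:
    """Full dynamical state of the coupled DNA + SMCC system."""

    # composition
    dna: DNAPolymer
    smcc: SMCCGeometry
    n_dna: int
    smcc_offset: int
    # per-bead arrays
    pos: np.ndarray
    vel: np.ndarray
    mass: np.ndarray
    mobility: np.ndarray          # 0 frozen, 1 free, 2 rigid-body bead
    body_of: np.ndarray
    bead_class: np.ndarray
    # rigid bodies
    n_bodies: int
    bmass: np.ndarray
    binert: np.ndarray            # principal inertia (nb, 3)
    bcom: np.ndarray
    bquat: np.ndarray
    bvel: np.ndarray
    bang: np.ndarray              # space-frame angular momentum
    Xb: np.ndarray                # body-frame bead coordinates
    # bonded terms
    bond_ij: np.ndarray
    bond_kind: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    bond_rmax: np.ndarray
    ang_ijk: np.ndarray
    ang_kappa: np.ndarray
    ang_th0: np.ndarray
    n_dna_angles: int
    dih_ijkl: np.ndarray
    dih_kappa: np.ndarray
    dih_phi0: np.ndarray
    # pair interactions (WCA core + attractive tail decomposition)
    peps_rep: np.ndarray
    peps_att: np.ndarray
    psig2: np.ndarray
    prc2: np.ndarray
    pshift: np.ndarray
    rlist2: np.ndarray
    excl_a: int
    excl_b: int
    nl_i: np.ndarray
    nl_j: np.ndarray
    n_pairs: np.ndarray
    ref_pos: np.ndarray
    # external forces / restraints
    fext: np.ndarray
    racc: np.ndarray
    racc_steps: int = 0
    # bookkeeping
    smcc_state_index: int = 0
    table: ff.ForceFieldTable = None
    time: float = 0.0             # nLsec
    rng_state: np.ndarray = None  # splitmix64 state for the thermostat
    dna_anchor_bead: int = -1
    # global indices of the binding sites / anchors / ring
    top_att: np.ndarray = None
    mid_att: np.ndarray = None
    bot_att: np.ndarray = None
    anchor_bead: int = -1
    ring: np.ndarray = None
    meta: dict = field(default_factory=dict)

    # -- convenience -----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    def dna_positions(self) -> np.ndarray:
        return self.pos[:self.n_dna]

    def smcc_positions(self) -> np.ndarray:
        return self.pos[self.n_dna:]

    def seed_thermostat(self, seed: int) -> None:
        self.rng_state = np.array([np.uint64(seed) ^ np.uint64(0x5DEECE66D)],
                                  dtype=np.uint64)

    def apply_table(self, table: ff.ForceFieldTable) -> None:
        """Install a state's interaction table (equilibria + pair matrix)."""
        self.table = table
        self.smcc_state_index = table.state_index
        self.ang_th0[self.n_dna_angles:] = table.angle_theta0
        self.dih_phi0[:] = table.dihedral_phi0
        rep, att = table.effective_pair_eps()
        sig = table.pair_sigma
        att_capable = (ff.CLASS_TOP_ATT, ff.CLASS_MID_ATT, ff.CLASS_BOT_ATT)
        for c in range(ff.N_CLASSES):
            self.peps_rep[c] = rep[c]
            self.peps_att[c] = att[c]
            self.psig2[c] = sig[c] * sig[c]
            if c in att_capable:
                rc = ff.ATT_CUTOFF_FACTOR * sig[c]
                sr6 = (sig[c] / rc) ** 6
                self.pshift[c] = 4.0 * (sr6 * sr6 - sr6)  # unit-depth shift
            else:
                rc = 2.0 ** (1.0 / 6.0) * sig[c]
                self.pshift[c] = -1.0
            self.prc2[c] = rc * rc

    def set_bridge_scale(self, scale: float) -> None:
        self.table.bridge_scale = float(scale)
        self.apply_table(self.table)

    def freeze_beads(self, indices) -> None:
        self.mobility[np.asarray(indices, dtype=np.int64)] = 0

    def rebuild_neighbor_list(self) -> None:
        np_ = K.build_neighbor_list(self.pos, self.bead_class, self.n_dna,
                                    self.rlist2, self.excl_a, self.excl_b,
                                    self.nl_i, self.nl_j)
        if np_ < 0:
            self._grow_nl()
            return self.rebuild_neighbor_list()
        self.n_pairs[0] = np_
        self.ref_pos[:] = self.pos

    def _grow_nl(self) -> None:
        cap = 2 * self.nl_i.shape[0]
        self.nl_i = np.zeros(cap, dtype=np.int64)
        self.nl_j = np.zeros(cap, dtype=np.int64)

    def compute_forces(self) -> np.ndarray:
        """Conservative forces at the current configuration."""
        self.rebuild_neighbor_list()
        f = np.zeros_like(self.pos)
        K.compute_forces(self.pos, f, self.bond_ij, self.bond_kind,
                         self.bond_k, self.bond_r0, self.bond_rmax,
                         self.ang_ijk, self.ang_kappa, self.ang_th0,
                         self.dih_ijkl, self.dih_kappa, self.dih_phi0,
                         self.bead_class, self.n_dna, self.peps_rep,
                         self.peps_att, self.psig2, self.prc2, self.pshift,
                         self.nl_i, self.nl_j, int(self.n_pairs[0]),
                         self.fext)
        return f

    def potential_energy(self) -> float:
        self.rebuild_neighbor_list()
        return float(K.compute_energy(
            self.pos, self.bond_ij, self.bond_kind, self.bond_k,
            self.bond_r0, self.bond_rmax, self.ang_ijk, self.ang_kappa,
            self.ang_th0, self.dih_ijkl, self.dih_kappa, self.dih_phi0,
            self.bead_class, self.n_dna, self.peps_rep, self.peps_att,
            self.psig2, self.prc2, self.pshift, self.nl_i, self.nl_j,
            int(self.n_pairs[0])))

    def sync_bodies_from_beads(self) -> None:
        """Recompute body centres/orientations after direct position edits."""
        _init_bodies(self)

    def clone(self) -> "SystemState":
        """Independent deep copy (shares only the immutable geometry)."""
        import copy

        dna, smcc = self.dna, self.smcc
        self.dna = self.smcc = None
        try:
            new = copy.deepcopy(self)
        finally:
            self.dna, self.smcc = dna, smcc
        new.dna, new.smcc = dna, smcc
        return new


def assemble_system(dna: DNAPolymer | None, smcc: SMCCGeometry | None,
                    smcc_state_index: int = 0,
                    dna_anchor_bead: int = -1) -> SystemState:
    """Merge a DNA polymer and/or an SMCC into a SystemState.

    Either component may be omitted (bare DNA runs; DNA-free futile
    cycling of the SMCC).
    """
    if dna is None:
        from .model_builder import DNAParameters
        dna = DNAPolymer(DNAParameters(beads=2),
                         np.zeros((0, 3)))
    n_dna = dna.positions.shape[0]
    dna_mass = ag_to_mass(dna.params.bead_mass_ag)
    if smcc is not None:
        n_smcc = smcc.n_beads
        pos = np.vstack([dna.positions, smcc.positions_by_state[smcc_state_index]])
        mass = np.concatenate([np.full(n_dna, dna_mass), smcc.bead_mass])
        body_of = np.concatenate([np.full(n_dna, -1, dtype=np.int64),
                                  smcc.body_id.astype(np.int64)])
        bead_class = np.concatenate([np.zeros(n_dna, dtype=np.int64),
                                     smcc.bead_class])
        n_bodies = 7
    else:
        n_smcc = 0
        pos = dna.positions.copy()
        mass = np.full(n_dna, dna_mass)
        body_of = np.full(n_dna, -1, dtype=np.int64)
        bead_class = np.zeros(n_dna, dtype=np.int64)
        n_bodies = 0
    n = n_dna + n_smcc
    off = n_dna

    mobility = np.where(body_of >= 0, 2, 1).astype(np.int8)

    # ---- bonds ----------------------------------------------------------
    nbd = max(n_dna - 1, 0)
    bi = [np.column_stack([np.arange(nbd), np.arange(1, nbd + 1)])]
    bkind = [np.ones(nbd, dtype=np.int64)]
    bk = [np.full(nbd, ff.BOND_K)]
    br0 = [np.full(nbd, ff.BOND_REST)]
    brm = [np.full(nbd, ff.BOND_MAX_EXT)]
    excl_a = excl_b = -1
    if smcc is not None:
        bi.append(smcc.bonds + off)
        nb = smcc.bonds.shape[0]
        bkind.append(np.zeros(nb, dtype=np.int64))
        bk.append(np.full(nb, ff.BODY_BOND_K))
        br0.append(smcc.bond_r0)
        brm.append(np.full(nb, 1.0))
        if dna_anchor_bead >= 0:
            anchor_global = off + smcc.anchor_bead
            bi.append(np.array([[dna_anchor_bead, anchor_global]]))
            bkind.append(np.zeros(1, dtype=np.int64))
            bk.append(np.array([ff.SAFETY_BELT_K]))
            br0.append(np.array([ff.SAFETY_BELT_REST]))
            brm.append(np.array([1.0]))
            excl_a, excl_b = dna_anchor_bead, anchor_global
    bond_ij = np.vstack(bi).astype(np.int64)
    bond_kind = np.concatenate(bkind)
    bond_k = np.concatenate(bk)
    bond_r0 = np.concatenate(br0)
    bond_rmax = np.concatenate(brm)

    # ---- angles ---------------------------------------------------------
    kappa_dna = ff.calibrate_dna_bending_kappa(
        dna.params.persistence_length, dna.params.bond_length)
    nad = max(n_dna - 2, 0)
    ai = [np.column_stack([np.arange(nad), np.arange(1, nad + 1),
                           np.arange(2, nad + 2)])]
    ak = [np.full(nad, kappa_dna)]
    at0 = [np.full(nad, math.pi)]
    n_dna_angles = nad
    if smcc is not None:
        ai.append(smcc.angles + off)
        ak.append(smcc.angle_kappa)
        at0.append(smcc.angle_theta0_by_state[:, smcc_state_index])
    ang_ijk = np.vstack(ai).astype(np.int64)
    ang_kappa = np.concatenate(ak)
    ang_th0 = np.concatenate(at0)

    if smcc is not None:
        dih_ijkl = (smcc.dihedrals + off).astype(np.int64)
        dih_kappa = smcc.dihedral_kappa.copy()
        dih_phi0 = smcc.dihedral_phi0_by_state[:, smcc_state_index].copy()
    else:
        dih_ijkl = np.zeros((0, 4), dtype=np.int64)
        dih_kappa = np.zeros(0)
        dih_phi0 = np.zeros(0)

    # ---- pair matrix and neighbour list ---------------------------------
    rmax_by_class = np.array([
        ff.DNA_DIAMETER,
        ff._WCA_FACTOR * ff.SIGMA_PD,
        ff.ATT_CUTOFF_FACTOR * ff.SIGMA_PD,
        ff.ATT_CUTOFF_FACTOR * ff.SIGMA_PD,
        ff.ATT_CUTOFF_FACTOR * ff.SIGMA_PD,
        ff._WCA_FACTOR * ff.SIGMA_PD,
    ])
    rlist2 = (rmax_by_class + NEIGHBOR_SKIN) ** 2
    cap = 64 * n + 4096
    state = SystemState(
        dna=dna, smcc=smcc, n_dna=n_dna, smcc_offset=off,
        pos=pos, vel=np.zeros_like(pos), mass=mass, mobility=mobility,
        body_of=body_of, bead_class=bead_class,
        n_bodies=n_bodies,
        bmass=np.zeros(max(n_bodies, 1)),
        binert=np.ones((max(n_bodies, 1), 3)),
        bcom=np.zeros((max(n_bodies, 1), 3)),
        bquat=np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (max(n_bodies, 1), 1)),
        bvel=np.zeros((max(n_bodies, 1), 3)),
        bang=np.zeros((max(n_bodies, 1), 3)),
        Xb=np.zeros_like(pos),
        bond_ij=bond_ij, bond_kind=bond_kind, bond_k=bond_k,
        bond_r0=bond_r0, bond_rmax=bond_rmax,
        ang_ijk=ang_ijk, ang_kappa=ang_kappa, ang_th0=ang_th0,
        n_dna_angles=n_dna_angles,
        dih_ijkl=dih_ijkl, dih_kappa=dih_kappa, dih_phi0=dih_phi0,
        peps_rep=np.zeros(ff.N_CLASSES), peps_att=np.zeros(ff.N_CLASSES),
        psig2=np.ones(ff.N_CLASSES),
        prc2=np.ones(ff.N_CLASSES), pshift=np.zeros(ff.N_CLASSES),
        rlist2=rlist2, excl_a=excl_a, excl_b=excl_b,
        nl_i=np.zeros(cap, dtype=np.int64), nl_j=np.zeros(cap, dtype=np.int64),
        n_pairs=np.zeros(1, dtype=np.int64),
        ref_pos=pos.copy(),
        fext=np.zeros_like(pos), racc=np.zeros_like(pos),
        smcc_state_index=smcc_state_index,
        dna_anchor_bead=dna_anchor_bead,
        meta={"kappa_dna": kappa_dna},
    )
    if smcc is not None:
        state.top_att = off + smcc.top_att
        state.mid_att = off + smcc.mid_att
        state.bot_att = off + smcc.bot_att
        state.anchor_bead = off + smcc.anchor_bead
        state.ring = off + smcc.ring
        state.apply_table(ff.assemble_interaction_table(
            smcc, smcc_state_index, smcc.variant))
        _init_bodies(state)
    else:
        # bare DNA: a permissive all-repulsive table
        state.peps_rep[0] = 1.0
        state.psig2[0] = ff.SIGMA_DNA_DNA ** 2
        state.prc2[0] = (ff._WCA_FACTOR * ff.SIGMA_DNA_DNA) ** 2
        state.pshift[0] = -1.0
    state.seed_thermostat(0)
    state.rebuild_neighbor_list()
    return state


def _init_bodies(state: SystemState) -> None:
    """(Re)compute body masses, principal inertias, coms and quaternions
    from the current bead positions."""
    sphere = 0.4 * 0.75 ** 2  # bead spin inertia (2/5 m a^2 per unit mass)
    for b in range(state.n_bodies):
        idx = np.nonzero(state.body_of == b)[0]
        m = state.mass[idx]
        M = m.sum()
        com = (m[:, None] * state.pos[idx]).sum(axis=0) / M
        r = state.pos[idx] - com
        inertia = np.zeros((3, 3))
        for mi, ri in zip(m, r):
            inertia += mi * ((ri @ ri) * np.eye(3) - np.outer(ri, ri))
        inertia += np.eye(3) * sphere * M
        evals, evecs = np.linalg.eigh(inertia)
        if np.linalg.det(evecs) < 0:
            evecs[:, 0] = -evecs[:, 0]
        state.bmass[b] = M
        state.binert[b] = np.maximum(evals, 1e-12)
        state.bcom[b] = com
        state.bquat[b] = _rot_to_quat(evecs)
        state.Xb[idx] = r @ evecs  # = evecs.T applied to each r
    state.bvel[:state.n_bodies] = 0.0
    state.bang[:state.n_bodies] = 0.0


def relax(state: SystemState, niter: int = 10000, max_disp: float = 0.05,
          ftol: float = 5.0) -> int:
    """Steepest-descent clash removal of the free beads."""
    state.rebuild_neighbor_list()
    it = K.steepest_descent(
        niter, max_disp, ftol, state.pos, state.mobility, state.body_of,
        state.bond_ij, state.bond_kind, state.bond_k, state.bond_r0,
        state.bond_rmax, state.ang_ijk, state.ang_kappa, state.ang_th0,
        state.dih_ijkl, state.dih_kappa, state.dih_phi0,
        state.bead_class, state.n_dna, state.peps_rep, state.peps_att,
        state.psig2, state.prc2, state.pshift, state.rlist2, state.excl_a,
        state.excl_b, state.nl_i, state.nl_j, state.n_pairs, state.fext)
    if it < 0:
        state._grow_nl()
        return relax(state, niter, max_disp, ftol)
    state.rebuild_neighbor_list()
    return it
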