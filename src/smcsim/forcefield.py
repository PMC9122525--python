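"""Interaction terms and the state-dependent interaction table.

The energy model has four ingredients:

* truncated-and-shifted Lennard-Jones pair terms (purely repulsive
  "WCA" mode for excluded volume, attractive mode for the protein
  DNA-binding sites),
* finitely-extensible bonds with a harmonic-plus-logarithmic form,
* harmonic bending angles (DNA stiffness, arm elbows, bridge--arm
  joints),
* harmonic dihedrals (the asymmetric kleisin fold).

The DNA bending constant is calibrated numerically so that the discrete
chain (bond length 1.7 nm) has a persistence length of 50 nm; the
Kratky-Porod estimate ``kappa ~= Lp/b`` serves as the initial guess.

:func:`assemble_interaction_table` builds the per-state
:class:`ForceFieldTable` that the dynamics engine consumes: which
binding-site attractions are on, whether the ATPase-bridge excluded
volume is present, and the equilibrium angles of every inter-body
coupling for the current conformational state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

# --------------------------------------------------------------------------
# constants (energies in kBT, lengths in nm)
# --------------------------------------------------------------------------

#: binding-site well depths per bead
EPS_TOP = 3.2
EPS_MID = 3.2
EPS_BOT = 11.0

#: DNA effective diameter (DNA-DNA excluded volume contact distance)
DNA_DIAMETER = 3.5
#: protein bead diameter
PROTEIN_DIAMETER = 1.5
#: protein-DNA contact distance (mixed radii)
PD_DIAMETER = 0.5 * (DNA_DIAMETER + PROTEIN_DIAMETER)

_WCA_FACTOR = 2.0 ** (1.0 / 6.0)
#: LJ sigma chosen so the repulsive-only potential vanishes at the
#: contact distance
SIGMA_DNA_DNA = DNA_DIAMETER / _WCA_FACTOR
SIGMA_PD = PD_DIAMETER / _WCA_FACTOR
#: attraction range, in units of sigma (short-range, saturating binding)
ATT_CUTOFF_FACTOR = 2.5

#: DNA bond (finitely extensible, harmonic-plus-logarithmic)
BOND_REST = 1.7
BOND_K = 100.0          # kBT/nm^2; RMS fluctuation sqrt(kT/K) = 0.1 nm
BOND_MAX_EXT = 0.5      # nm, divergence bound either side of the rest length

#: stiff harmonic bonds joining SMCC rigid bodies
BODY_BOND_K = 100.0

#: angular stiffnesses (kBT/rad^2)
KAPPA_ELBOW = 30.0
KAPPA_ARM_BEND = 30.0
KAPPA_BRIDGE_ARM = 100.0
KAPPA_KLEISIN_DIH = (60.0, 100.0)

#: safety-belt anchor bond
SAFETY_BELT_K = 100.0
SAFETY_BELT_REST = 1.5

#: DNA persistence length target
PERSISTENCE_LENGTH = 50.0

#: bead classes for the pair-interaction matrix
CLASS_DNA = 0
CLASS_PROT_REP = 1      # arms + repulsive hinge/kleisin beads
CLASS_TOP_ATT = 2
CLASS_MID_ATT = 3       # lives on the bridge body: EV follows the bridge
CLASS_BOT_ATT = 4
CLASS_BRIDGE_REP = 5
N_CLASSES = 6

STATE_NAMES = {0: "apo", 1: "ATP", 2: "ADP"}


class SingularSeparationError(ValueError):
    """Raised when a pair distance of exactly zero is requested."""


class OverstretchError(ValueError):
    """Raised when a bond is evaluated at or beyond its extension bound."""


# --------------------------------------------------------------------------
# pair terms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTerm:
    """A truncated-and-shifted Lennard-Jones interaction.

    ``mode="repulsive"`` cuts at the potential minimum (WCA);
    ``mode="attractive"`` cuts at ``ATT_CUTOFF_FACTOR * sigma``.
    The potential is shifted so it is exactly zero at the cutoff.
    """

    epsilon: float
    sigma: float
    mode: str = "repulsive"

    @property
    def rcut(self) -> float:
        if self.mode == "repulsive":
            return _WCA_FACTOR * self.sigma
        return ATT_CUTOFF_FACTOR * self.sigma

    @property
    def shift(self) -> float:
        if self.mode == "repulsive":
            return -self.epsilon
        sr6 = (self.sigma / self.rcut) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)


def pair_energy_force(r: float, term: PairTerm) -> tuple[float, float]:
    """Energy and radial force magnitude ``-dU/dr`` of a pair term at r."""
    if r <= 0.0:
        raise SingularSeparationError("pair separation must be positive")
    if r >= term.rcut or term.epsilon == 0.0:
        return 0.0, 0.0
    sr6 = (term.sigma / r) ** 6
    energy = 4.0 * term.epsilon * (sr6 * sr6 - sr6) - term.shift
    force = 24.0 * term.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return energy, force


# --------------------------------------------------------------------------
# bonded terms
# --------------------------------------------------------------------------

def bond_energy_force(
    r: float,
    k: float = BOND_K,
    r0: float = BOND_REST,
    rmax: float = BOND_MAX_EXT,
) -> tuple[float, float]:
    """Finitely-extensible bond: ``U = -k*rmax^2/2 * ln(1 - (dr/rmax)^2)``.

    Harmonic (stiffness ``k``) near the rest length, diverging at
    ``r0 +/- rmax``.  Returns ``(energy, -dU/dr)``.
    """
    dr = r - r0
    x2 = (dr / rmax) ** 2
    if x2 >= 1.0:
        raise OverstretchError(f"bond length {r} at/beyond extensibility bound")
    energy = -0.5 * k * rmax * rmax * math.log1p(-x2)
    force = -k * dr / (1.0 - x2)
    return energy, force


def angle_energy_force(theta: float, kappa: float, theta0: float) -> tuple[float, float]:
    """Harmonic angle term.  Returns ``(energy, torque = -dU/dtheta)``."""
    d = theta - theta0
    return 0.5 * kappa * d * d, -kappa * d


def dihedral_energy_force(phi: float, kappa: float, phi0: float) -> tuple[float, float]:
    """Harmonic dihedral, periodic-wrapped difference.  Returns (E, -dU/dphi)."""
    d = math.remainder(phi - phi0, 2.0 * math.pi)
    return 0.5 * kappa * d * d, -kappa * d


# --------------------------------------------------------------------------
# DNA bending calibration
# --------------------------------------------------------------------------

def _mean_cos_bend(kappa: float) -> float:
    """<cos gamma> for bend angle gamma with weight sin(g)*exp(-kappa g^2/2)."""
    num = quad(lambda g: math.cos(g) * math.sin(g) * math.exp(-0.5 * kappa * g * g),
               0.0, math.pi, limit=200)[0]
    den = quad(lambda g: math.sin(g) * math.exp(-0.5 * kappa * g * g),
               0.0, math.pi, limit=200)[0]
    return num / den


def persistence_length_of_kappa(kappa: float, bond: float = BOND_REST) -> float:
    """Persistence length (nm) of the discrete chain with bending kappa."""
    return -bond / math.log(_mean_cos_bend(kappa))


@lru_cache(maxsize=None)
def calibrate_dna_bending_kappa(
    lp: float = PERSISTENCE_LENGTH, bond: float = BOND_REST
) -> float:
    """Bending stiffness (kBT/rad^2) giving persistence length ``lp``.

    Solved numerically; the Kratky-Porod estimate ``lp/bond`` brackets
    the root from below because the sin(theta) measure softens the chain.
    """
    guess = lp / bond
    return brentq(lambda k: persistence_length_of_kappa(k, bond) - lp,
                  0.5 * guess, 3.0 * guess, xtol=1e-10)


# --------------------------------------------------------------------------
# state-dependent interaction table
# --------------------------------------------------------------------------

@dataclass
class ForceFieldTable:
    """All state-dependent interaction parameters for one SMCC state.

    The DNA-vs-class pair matrix (index = bead class; entry 0 is
    DNA-DNA) is stored in a WCA-core + attractive-tail decomposition:
    ``U = eps_rep * WCA(r) + eps_att * TAIL(r)``.  With
    ``eps_rep == eps_att`` this is exactly the truncated-shifted
    Lennard-Jones of depth ``eps_att``; with ``eps_att == 0`` it is
    purely repulsive.  Binding-site switching therefore only moves these
    two scalars, never the beads, and conformational transitions can
    ramp them continuously.  ``bridge_scale`` multiplies the bridge-body
    entries (0 while the bridge is absent).
    Equilibrium angles for the SMCC inter-body couplings are stored per
    term, aligned with the geometry's term lists.
    """

    state_index: int
    pair_eps_rep: np.ndarray
    pair_eps_att: np.ndarray
    pair_sigma: np.ndarray
    bridge_on: bool
    bridge_scale: float
    angle_theta0: np.ndarray
    dihedral_phi0: np.ndarray
    notes: dict = field(default_factory=dict)

    def effective_pair_eps(self) -> tuple[np.ndarray, np.ndarray]:
        """(eps_rep, eps_att) with the bridge ramp applied."""
        rep = self.pair_eps_rep.copy()
        att = self.pair_eps_att.copy()
        for c in (CLASS_MID_ATT, CLASS_BRIDGE_REP):
            rep[c] *= self.bridge_scale
            att[c] *= self.bridge_scale
        return rep, att


def site_epsilons(state_index: int, variant=None) -> tuple[float, float, float]:
    """(top, middle, bottom) well depths for a given state and variant.

    apo: only the bottom site is on.  ATP: top+middle+bottom on, bridge
    present.  ADP: middle and bottom off (top stays on until the return
    to apo).  Variant flags force the top/middle attractions off in all
    states.
    """
    if state_index == 0:
        eps = [0.0, 0.0, EPS_BOT]
    elif state_index == 1:
        eps = [EPS_TOP, EPS_MID, EPS_BOT]
    elif state_index == 2:
        eps = [EPS_TOP, 0.0, 0.0]
    else:
        raise ValueError(f"unknown SMCC state {state_index!r}")
    if variant is not None:
        if getattr(variant, "no_top_site", False):
            eps[0] = 0.0
        if getattr(variant, "no_middle_site", False):
            eps[1] = 0.0
    return tuple(eps)


def assemble_interaction_table(geom, state_index: int, variant=None) -> ForceFieldTable:
    """Build the :class:`ForceFieldTable` for ``state_index``.

    ``geom`` is a :class:`~smcsim.model_builder.SMCCGeometry`; its
    per-state equilibrium-angle arrays supply the bonded equilibria.
    Binding-site switching toggles the attraction entries of the pair
    matrix (never removes beads); the bridge excluded volume is present
    only in the ATP-bound state.
    """
    if state_index not in (0, 1, 2):
        raise ValueError(f"unknown SMCC state {state_index!r}")
    variant = variant if variant is not None else geom.variant
    e_top, e_mid, e_bot = site_epsilons(state_index, variant)
    bridge_on = state_index == 1

    rep = np.zeros(N_CLASSES)
    att = np.zeros(N_CLASSES)
    sigma = np.zeros(N_CLASSES)

    rep[CLASS_DNA] = 1.0
    sigma[CLASS_DNA] = SIGMA_DNA_DNA
    sigma[CLASS_PROT_REP:] = SIGMA_PD
    rep[CLASS_PROT_REP] = 1.0
    # site beads: full LJ of the site depth when active (eps_rep ==
    # eps_att), plain unit WCA when switched off
    for cls, e in ((CLASS_TOP_ATT, e_top), (CLASS_MID_ATT, e_mid),
                   (CLASS_BOT_ATT, e_bot)):
        if e > 0.0:
            rep[cls] = e
            att[cls] = e
        else:
            rep[cls] = 1.0
    # the bridge body (repulsive beads + middle site) exists only when the
    # ATPase heads are engaged
    rep[CLASS_BRIDGE_REP] = 1.0
    if not bridge_on:
        rep[CLASS_MID_ATT] = 0.0
        att[CLASS_MID_ATT] = 0.0
        rep[CLASS_BRIDGE_REP] = 0.0

    return ForceFieldTable(
        state_index=state_index,
        pair_eps_rep=rep,
        pair_eps_att=att,
        pair_sigma=sigma,
        bridge_on=bridge_on,
        bridge_scale=1.0,
        angle_theta0=geom.angle_theta0_by_state[:, state_index].copy(),
        dihedral_phi0=geom.dihedral_phi0_by_state[:, state_index].copy(),
        notes={
            "state": STATE_NAMES[state_index],
            "eps_top": e_top, "eps_mid": e_mid, "eps_bot": e_bot,
        },
    )


def dump_table(table: ForceFieldTable, geom, path) -> None:
    """Write a human-readable force-field table for reproducibility."""
    lines = [f"# force-field table, SMCC state {table.state_index} "
             f"({STATE_NAMES[table.state_index]})"]
    lines.append("## pair matrix (DNA vs bead class)")
    names = ["DNA", "PROT_REP", "TOP_ATT", "MID_ATT", "BOT_ATT", "BRIDGE_REP"]
    for c, name in enumerate(names):
        m = "attractive" if table.pair_eps_att[c] > 0 else "repulsive"
        lines.append(f"  {name:<11s} eps_rep={table.pair_eps_rep[c]:6.3f} "
                     f"eps_att={table.pair_eps_att[c]:6.3f} kBT  "
                     f"sigma={table.pair_sigma[c]:.4f} nm  ({m})")
    lines.append(f"  bridge_on={table.bridge_on} bridge_scale={table.bridge_scale}")
    lines.append("## SMCC inter-body angles (kappa kBT/rad^2, theta0 deg)")
    for lbl, kappa, th0 in zip(geom.angle_labels, geom.angle_kappa,
                               table.angle_theta0):
        lines.append(f"  {lbl:<24s} kappa={kappa:6.1f} theta0={math.degrees(th0):8.2f}")
    lines.append("## kleisin dihedrals (kappa kBT/rad^2, phi0 deg)")
    for lbl, kappa, ph0 in zip(geom.dihedral_labels, geom.dihedral_kappa,
                               table.dihedral_phi0):
        lines.append(f"  {lbl:<24s} kappa={kappa:6.1f} phi0={math.degrees(ph0):8.2f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
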