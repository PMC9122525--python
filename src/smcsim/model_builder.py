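"""Construction of the DNA polymer and the SMC-complex rigid-body assembly.

The SMC complex (SMCC) is built from 7 rigid bodies: four coiled-coil arm
segments (hinge-to-elbow and elbow-to-head, 25 nm each), the hinge body
carrying the *top* DNA-binding site, the ATPase bridge carrying the
*middle* site, and the kleisin arc carrying the *bottom* site and the
exterior safety-belt anchor.  Bodies are coupled by stiff bonds plus
harmonic angles/dihedrals whose equilibria depend on the conformational
state:

* state 0 (apo): arms closed, bridge excluded volume off, kleisin
  compartment folded by 45 degrees, only the bottom site attractive;
* state 1 (ATP): arms open, bridge on, kleisin folded by 160 degrees
  (the power stroke), top+middle+bottom sites attractive;
* state 2 (ADP): arms open, bridge off, fold back to 45 degrees,
  middle+bottom off (top stays on until the return to apo).

Geometry convention: the ring of arms+kleisin lies in the y-z plane with
the hinge at +z; DNA is threaded along x.  The kleisin fold is a
rotation about the head-head (y) axis *towards +x*, which breaks
left-right symmetry along the DNA and sets the translocation direction.

Each state's bead coordinates are constructed explicitly as that state's
minimal-energy conformation; the equilibrium values of every inter-body
angle and dihedral are then *measured* from those coordinates, which
keeps the bonded terms exactly consistent with the intended shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import forcefield as ff
from .units import ag_to_mass

# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

ARM_SEGMENT_LENGTH = 25.0       # nm, hinge-elbow and elbow-head
ARM_SEGMENT_LENGTH_SHORT = 20.0  # nm, "shorter arms" variant
ARM_OPEN_ANGLE_DEG = 25.0       # lower-arm out-tilt from vertical, open states
HEAD_HALF_SEP = 3.75            # heads at y = +/- 3.75 (7.5 nm bridge)
BRIDGE_LENGTH = 7.5
KLEISIN_RADIUS = 7.0
KLEISIN_FOLD_APO_DEG = 45.0
KLEISIN_FOLD_ATP_DEG = 160.0
KLEISIN_FOLD_ATP_LESS_DEG = 130.0
SMCC_TOTAL_MASS_AG = 0.25
MAX_ARM_BEAD_SPACING = 1.5      # one bead diameter: ring impenetrable to DNA

BODY_NAMES = ("armUL", "armUR", "armLL", "armLR", "topSite", "bridge", "kleisin")
ARM_UL, ARM_UR, ARM_LL, ARM_LR, TOP, BRIDGE, KLEISIN = range(7)


class InvalidParameterError(ValueError):
    pass


class InitializationFailure(RuntimeError):
    pass


# --------------------------------------------------------------------------
# DNA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DNAParameters:
    """Discretized worm-like-chain parameters (5 bp per bead)."""

    beads: int = 301
    bp_per_bead: int = 5
    bond_length: float = 1.7        # nm
    persistence_length: float = 50.0  # nm
    diameter: float = 3.5           # nm, effective at physiological salt
    bead_mass_ag: float = 0.005     # ag (3 kDa per 5 bp)

    @property
    def contour_length(self) -> float:
        return (self.beads - 1) * self.bond_length

    @property
    def length_bp(self) -> int:
        return self.beads * self.bp_per_bead


@dataclass
class DNAPolymer:
    """Bead positions and implicit consecutive-bead bonds."""

    params: DNAParameters
    positions: np.ndarray  # (beads, 3)

    @property
    def n_beads(self) -> int:
        return self.params.beads

    @property
    def contour_length(self) -> float:
        return self.params.contour_length

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


def build_dna(params: DNAParameters = DNAParameters(),
              conformation: str = "straight",
              seed: int = 0) -> DNAPolymer:
    """Build a DNA polymer, either straight along +x or thermalized.

    The thermalized conformation is drawn by sequential bond-angle
    sampling from the bending Boltzmann weight
    ``P(g) ~ sin(g) exp(-kappa g^2 / 2)`` with uniform azimuth, which is
    the exact equilibrium ensemble of the chain's bending degrees of
    freedom (excluded volume neglected at this stage).
    """
    if params.beads < 2:
        raise InvalidParameterError("a DNA polymer needs at least 2 beads")
    n, b = params.beads, params.bond_length
    if conformation == "straight":
        x = (np.arange(n) - (n - 1) / 2.0) * b
        pos = np.column_stack([x, np.zeros(n), np.zeros(n)])
        return DNAPolymer(params, pos)
    if conformation != "thermalized":
        raise InvalidParameterError(f"unknown conformation {conformation!r}")

    rng = np.random.default_rng(seed)
    kappa = ff.calibrate_dna_bending_kappa(params.persistence_length, b)
    bends = _sample_bend_angles(kappa, n - 2, rng)
    tangents = np.empty((n - 1, 3))
    tangents[0] = (1.0, 0.0, 0.0)
    for i in range(1, n - 1):
        tangents[i] = _rotate_tangent(tangents[i - 1], bends[i - 1],
                                      rng.uniform(0.0, 2.0 * math.pi))
    pos = np.vstack([np.zeros(3), np.cumsum(b * tangents, axis=0)])
    return DNAPolymer(params, pos - pos.mean(axis=0))


def _sample_bend_angles(kappa: float, count: int, rng) -> np.ndarray:
    """Rejection-sample bend angles from sin(g)*exp(-kappa g^2/2).

    Proposal: Rayleigh with scale 1/sqrt(kappa) (density ~ g exp(-k g^2/2)),
    accepted with probability sin(g)/g <= 1.
    """
    out = np.empty(count)
    got = 0
    while got < count:
        m = max(64, 2 * (count - got))
        g = rng.rayleigh(scale=1.0 / math.sqrt(kappa), size=m)
        keep = g[(g < math.pi)
                 & (rng.uniform(size=m) < np.sin(np.minimum(g, math.pi)) / g)]
        take = min(keep.size, count - got)
        out[got:got + take] = keep[:take]
        got += take
    return out


def _rotate_tangent(t: np.ndarray, bend: float, azimuth: float) -> np.ndarray:
    """Rotate unit vector t by ``bend`` in a random azimuthal direction."""
    # orthonormal frame around t
    a = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    new = (math.cos(bend) * t
           + math.sin(bend) * (math.cos(azimuth) * u + math.sin(azimuth) * v))
    return new / np.linalg.norm(new)


def sample_thermalized_tangents(params: DNAParameters, n_chains: int,
                                seed: int = 0) -> np.ndarray:
    """Vectorized equilibrium sampling of ``n_chains`` tangent sequences.

    Returns unit tangents of shape ``(n_chains, beads-1, 3)`` drawn from
    the bending Boltzmann weight; the workhorse behind large-ensemble
    persistence-length checks.
    """
    rng = np.random.default_rng(seed)
    kappa = ff.calibrate_dna_bending_kappa(params.persistence_length,
                                           params.bond_length)
    m, nt = n_chains, params.beads - 1
    bends = _sample_bend_angles(kappa, m * (nt - 1), rng).reshape(m, nt - 1)
    azim = rng.uniform(0.0, 2.0 * math.pi, size=(m, nt - 1))
    t = np.zeros((m, nt, 3))
    t[:, 0] = (1.0, 0.0, 0.0)
    zhat = np.array([0.0, 0.0, 1.0])
    xhat = np.array([1.0, 0.0, 0.0])
    for i in range(1, nt):
        cur = t[:, i - 1]
        ref = np.where(np.abs(cur[:, 2:3]) < 0.9, zhat, xhat)
        u = np.cross(cur, ref)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(cur, u)
        g = bends[:, i - 1:i]
        a = azim[:, i - 1:i]
        new = (np.cos(g) * cur
               + np.sin(g) * (np.cos(a) * u + np.sin(a) * v))
        t[:, i] = new / np.linalg.norm(new, axis=1, keepdims=True)
    return t


def fit_persistence_length_tangents(tangents: np.ndarray, bond: float,
                                    max_sep: int = 25) -> float:
    """Tangent-correlation Lp fit on an ``(m, nt, 3)`` tangent ensemble."""
    corr = np.empty(max_sep)
    for k in range(1, max_sep + 1):
        corr[k - 1] = np.einsum("mij,mij->", tangents[:, :-k],
                                tangents[:, k:]) / (
            tangents.shape[0] * (tangents.shape[1] - k))
    s = np.arange(1, max_sep + 1) * bond
    good = corr > 0
    slope = np.polyfit(s[good], np.log(corr[good]), 1)[0]
    return -1.0 / slope


def fit_persistence_length(ensemble: list[np.ndarray], bond: float,
                           max_sep: int = 25) -> float:
    """Tangent-correlation persistence length from an ensemble of chains.

    Fits ``<t(s).t(0)> = exp(-s/Lp)`` by linear regression of
    ``log <t_i . t_{i+k}>`` against contour separation ``k*bond``.
    """
    sums = np.zeros(max_sep + 1)
    counts = np.zeros(max_sep + 1)
    for pos in ensemble:
        t = np.diff(pos, axis=0)
        t /= np.linalg.norm(t, axis=1)[:, None]
        for k in range(1, max_sep + 1):
            c = np.einsum("ij,ij->i", t[:-k], t[k:])
            sums[k] += c.sum()
            counts[k] += c.size
    corr = sums[1:] / counts[1:]
    s = np.arange(1, max_sep + 1) * bond
    good = corr > 0
    slope = np.polyfit(s[good], np.log(corr[good]), 1)[0]
    return -1.0 / slope


# --------------------------------------------------------------------------
# SMCC variants and geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """Composable structural-variant flags (default: all off)."""

    no_top_site: bool = False
    no_middle_site: bool = False
    shorter_arms: bool = False
    less_folding: bool = False
    floppy_elbow: bool = False

    def label(self) -> str:
        on = [k for k, v in self.__dict__.items() if v]
        return "+".join(on) if on else "default"


@dataclass
class SMCCGeometry:
    """The 7-rigid-body SMC complex.

    Positions are stored for the construction state ``state_index``
    (that state's minimal-energy conformation); ``positions_by_state``
    keeps all three reference conformations, from which the per-state
    equilibrium angles were measured.
    Bead bookkeeping uses local indices 0..n_beads-1.
    """

    variant: VariantSpec
    state_index: int
    positions: np.ndarray            # (n, 3) construction-state coords
    positions_by_state: np.ndarray   # (3, n, 3)
    body_id: np.ndarray              # (n,) 0..6
    bead_class: np.ndarray           # (n,) forcefield classes
    bead_mass: np.ndarray            # (n,) internal units
    top_att: np.ndarray              # indices of attractive beads
    mid_att: np.ndarray
    bot_att: np.ndarray
    anchor_bead: int                 # designated exterior safety-belt bead
    # inter-body bonded terms (local indices)
    bonds: np.ndarray                # (nb, 2)
    bond_r0: np.ndarray
    angles: np.ndarray               # (na, 3)
    angle_kappa: np.ndarray
    angle_theta0_by_state: np.ndarray   # (na, 3)
    angle_labels: list = field(default_factory=list)
    dihedrals: np.ndarray = None     # (nd, 4)
    dihedral_kappa: np.ndarray = None
    dihedral_phi0_by_state: np.ndarray = None  # (nd, 3)
    dihedral_labels: list = field(default_factory=list)
    ring: np.ndarray = None          # ordered ring bead indices (topology)
    calibration: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def body_indices(self, body: int) -> np.ndarray:
        return np.nonzero(self.body_id == body)[0]

    def total_mass_ag(self) -> float:
        return SMCC_TOTAL_MASS_AG

    def fold_angle_deg(self, state_index: int) -> float:
        if state_index == 1:
            return (KLEISIN_FOLD_ATP_LESS_DEG if self.variant.less_folding
                    else KLEISIN_FOLD_ATP_DEG)
        return KLEISIN_FOLD_APO_DEG


def _fold_matrix(phi: float) -> np.ndarray:
    """Rotation about the head-head (y) axis carrying -z towards +x."""
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _segment_beads(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    """n cell-centred beads along the segment p0->p1 (ends inset)."""
    t = (np.arange(n) + 0.5) / n
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def _state_skeleton(state_index: int, variant: VariantSpec) -> dict:
    """Bead coordinates of every body for one conformational state."""
    La = ARM_SEGMENT_LENGTH_SHORT if variant.shorter_arms else ARM_SEGMENT_LENGTH
    n_arm = math.ceil(La / MAX_ARM_BEAD_SPACING)
    arms_open = state_index in (1, 2)

    head_l = np.array([0.0, -HEAD_HALF_SEP, 0.0])
    head_r = np.array([0.0, +HEAD_HALF_SEP, 0.0])

    if arms_open:
        beta = math.radians(ARM_OPEN_ANGLE_DEG)
        elbow_y = HEAD_HALF_SEP + La * math.sin(beta)
    else:
        # arms tilt inward so the elbows meet on the axis: closed ring
        beta = -math.asin(HEAD_HALF_SEP / La)
        elbow_y = 0.0
    elbow_z = La * math.cos(beta)
    elbow_l = np.array([0.0, -elbow_y, elbow_z])
    elbow_r = np.array([0.0, +elbow_y, elbow_z])

    # hinge plate: lower row of 9 beads (3 central attractive), upper row
    # of 8; arms attach at the upper-row ends
    att_y = 4.0
    dy = abs(elbow_y - att_y)
    if La <= dy:
        raise InvalidParameterError("arm too short for hinge geometry")
    zh = elbow_z + math.sqrt(La * La - dy * dy)
    att_l = np.array([0.0, -att_y, zh])
    att_r = np.array([0.0, +att_y, zh])

    arm_ul = _segment_beads(att_l, elbow_l, n_arm)
    arm_ur = _segment_beads(att_r, elbow_r, n_arm)
    arm_ll = _segment_beads(elbow_l, head_l, n_arm)
    arm_lr = _segment_beads(elbow_r, head_r, n_arm)

    top_upper = np.column_stack([np.zeros(8),
                                 np.linspace(-att_y, att_y, 8),
                                 np.full(8, zh)])
    top_lower = np.column_stack([np.zeros(9),
                                 np.linspace(-2.8, 2.8, 9),
                                 np.full(9, zh - 1.3)])
    top = np.vstack([top_upper, top_lower])
    top_att_local = np.array([8 + 3, 8 + 4, 8 + 5])  # y = -0.75, 0, +0.75

    # ATPase bridge: 8 beads along the head-head axis, the two central
    # ones attractive and raised to the upper face
    by = -HEAD_HALF_SEP + (np.arange(8) + 0.5) * BRIDGE_LENGTH / 8.0
    bridge = np.column_stack([np.zeros(8), by, np.zeros(8)])
    mid_att_local = np.array([3, 4])
    bridge[mid_att_local, 2] = 0.75

    # kleisin: major arc of a radius-7 circle hanging below the heads,
    # folded about the y axis towards +x
    c = math.sqrt(KLEISIN_RADIUS ** 2 - HEAD_HALF_SEP ** 2)
    centre = np.array([0.0, 0.0, -c])
    chi = math.atan2(HEAD_HALF_SEP, c)
    d_rep = (2.0 * math.pi - 2.0 * chi) / 14.0
    a_rep = chi + (np.arange(14) + 0.5) * d_rep
    kle_rep = centre + KLEISIN_RADIUS * np.column_stack(
        [np.zeros(14), np.sin(a_rep), np.cos(a_rep)])
    # bottom site: a 3-bead binding groove along the threading direction
    # (the arc-plane normal) at the pocket bottom, inset towards the
    # centre.  The groove clamps the motor's yaw while DNA is bound,
    # giving the orientation memory a processive motor needs.
    bottom = centre + (KLEISIN_RADIUS - 1.4) * np.array([0.0, 0.0, -1.0])
    kle_att = bottom[None, :] + np.array([[-2.2, 0.0, 0.0],
                                          [0.0, 0.0, 0.0],
                                          [+2.2, 0.0, 0.0]])
    kleisin = np.vstack([kle_rep, kle_att])

    if state_index == 1:
        fold = (KLEISIN_FOLD_ATP_LESS_DEG if variant.less_folding
                else KLEISIN_FOLD_ATP_DEG)
    else:
        fold = KLEISIN_FOLD_APO_DEG
    kleisin = kleisin @ _fold_matrix(math.radians(fold)).T

    return {
        "armUL": arm_ul, "armUR": arm_ur, "armLL": arm_ll, "armLR": arm_lr,
        "topSite": top, "bridge": bridge, "kleisin": kleisin,
        "top_att_local": top_att_local, "mid_att_local": mid_att_local,
        "kle_att_local": np.arange(14, 17),
        # anchor: repulsive arc bead far around the arc (-y side, near
        # the head attachment), maximizing its distance from the
        # bottom-site groove so the reactivated site cannot grab the
        # anchored slack instead of the threaded strand
        "anchor_local": 10,
        "n_arm": n_arm, "fold_deg": fold,
        "arm_open_deg": math.degrees(beta), "hinge_z": zh,
    }


def _angle(p, i, j, k) -> float:
    u, v = p[i] - p[j], p[k] - p[j]
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(min(1.0, max(-1.0, cosv)))


def _dihedral(p, i, j, k, l) -> float:
    b1, b2, b3 = p[j] - p[i], p[k] - p[j], p[l] - p[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(np.dot(m, n2), np.dot(n1, n2))


def build_smcc(variant: VariantSpec = VariantSpec(),
               state_index: int = 0) -> SMCCGeometry:
    """Build the SMCC in the minimal-energy conformation of a state."""
    if state_index not in (0, 1, 2):
        raise InvalidParameterError(f"unknown SMCC state {state_index!r}")

    skels = [_state_skeleton(s, variant) for s in (0, 1, 2)]
    n_arm = skels[0]["n_arm"]

    order = ["armUL", "armUR", "armLL", "armLR", "topSite", "bridge", "kleisin"]
    sizes = [n_arm, n_arm, n_arm, n_arm, 17, 8, 17]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_beads = offsets[-1]

    pos_by_state = np.empty((3, n_beads, 3))
    for s in range(3):
        pos_by_state[s] = np.vstack([skels[s][name] for name in order])

    body_id = np.concatenate([np.full(sz, b) for b, sz in enumerate(sizes)])
    bead_class = np.full(n_beads, ff.CLASS_PROT_REP, dtype=np.int64)
    off = dict(zip(order, offsets[:-1]))
    top_att = off["topSite"] + skels[0]["top_att_local"]
    mid_att = off["bridge"] + skels[0]["mid_att_local"]
    bot_att = off["kleisin"] + skels[0]["kle_att_local"]
    bead_class[top_att] = ff.CLASS_TOP_ATT
    bead_class[mid_att] = ff.CLASS_MID_ATT
    bead_class[bot_att] = ff.CLASS_BOT_ATT
    bead_class[off["bridge"]:off["bridge"] + 8] = ff.CLASS_BRIDGE_REP
    bead_class[mid_att] = ff.CLASS_MID_ATT
    anchor_bead = off["kleisin"] + skels[0]["anchor_local"]

    mass = np.full(n_beads, ag_to_mass(SMCC_TOTAL_MASS_AG) / n_beads)

    # ---- inter-body couplings ------------------------------------------
    aul, aur = off["armUL"], off["armUR"]
    all_, alr = off["armLL"], off["armLR"]
    topo, bro, klo = off["topSite"], off["bridge"], off["kleisin"]
    up_row = topo  # first 8 beads are the upper row
    # key beads
    ul_top, ul_bot = aul, aul + n_arm - 1          # hinge end, elbow end
    ur_top, ur_bot = aur, aur + n_arm - 1
    ll_top, ll_bot = all_, all_ + n_arm - 1        # elbow end, head end
    lr_top, lr_bot = alr, alr + n_arm - 1
    kle_l, kle_r = klo + 13, klo + 0               # arc ends (-y / +y side)

    bonds = [
        (up_row + 0, ul_top), (up_row + 7, ur_top),
        (ul_bot, ll_top), (ur_bot, lr_top),
        (ll_bot, bro + 0), (lr_bot, bro + 7),
        (ll_bot, kle_l), (lr_bot, kle_r),
    ]

    kap_elbow = 0.0 if variant.floppy_elbow else ff.KAPPA_ELBOW
    angles = [
        # hinge attachments (arm bend)
        ((up_row + 1, up_row + 0, ul_top), ff.KAPPA_ARM_BEND, "hingeL_plate"),
        ((up_row + 0, ul_top, ul_top + 1), ff.KAPPA_ARM_BEND, "hingeL_arm"),
        ((up_row + 6, up_row + 7, ur_top), ff.KAPPA_ARM_BEND, "hingeR_plate"),
        ((up_row + 7, ur_top, ur_top + 1), ff.KAPPA_ARM_BEND, "hingeR_arm"),
        # elbows
        ((ul_bot - 1, ul_bot, ll_top), kap_elbow, "elbowL_upper"),
        ((ul_bot, ll_top, ll_top + 1), kap_elbow, "elbowL_lower"),
        ((ur_bot - 1, ur_bot, lr_top), kap_elbow, "elbowR_upper"),
        ((ur_bot, lr_top, lr_top + 1), kap_elbow, "elbowR_lower"),
        # bridge-arm joints (drive arm opening/closure)
        ((ll_bot - 1, ll_bot, bro + 0), ff.KAPPA_BRIDGE_ARM, "bridgeL_arm"),
        ((ll_bot, bro + 0, bro + 1), ff.KAPPA_BRIDGE_ARM, "bridgeL_axis"),
        ((lr_bot - 1, lr_bot, bro + 7), ff.KAPPA_BRIDGE_ARM, "bridgeR_arm"),
        ((lr_bot, bro + 7, bro + 6), ff.KAPPA_BRIDGE_ARM, "bridgeR_axis"),
        # kleisin attachment (keeps the arc ends at the heads)
        ((ll_bot - 1, ll_bot, kle_l), ff.KAPPA_BRIDGE_ARM, "kleisinL_attach"),
        ((lr_bot - 1, lr_bot, kle_r), ff.KAPPA_BRIDGE_ARM, "kleisinR_attach"),
    ]
    dihedrals = [
        # the asymmetric kleisin fold, measured about the head-head axis
        ((ll_bot - 1, ll_bot, lr_bot, klo + 2), ff.KAPPA_KLEISIN_DIH[0],
         "kleisin_fold_60"),
        ((lr_bot - 1, lr_bot, ll_bot, klo + 11), ff.KAPPA_KLEISIN_DIH[1],
         "kleisin_fold_100"),
    ]

    bond_arr = np.array([b for b in bonds], dtype=np.int64)
    bond_r0 = np.array([np.linalg.norm(pos_by_state[0, i] - pos_by_state[0, j])
                        for i, j in bonds])
    ang_arr = np.array([a for a, _, _ in angles], dtype=np.int64)
    ang_kappa = np.array([k for _, k, _ in angles])
    ang_labels = [lbl for _, _, lbl in angles]
    ang_th0 = np.empty((len(angles), 3))
    for s in range(3):
        for t, (ijk, _, _) in enumerate(angles):
            ang_th0[t, s] = _angle(pos_by_state[s], *ijk)
    dih_arr = np.array([d for d, _, _ in dihedrals], dtype=np.int64)
    dih_kappa = np.array([k for _, k, _ in dihedrals])
    dih_labels = [lbl for _, _, lbl in dihedrals]
    dih_ph0 = np.empty((len(dihedrals), 3))
    for s in range(3):
        for t, (ijkl, _, _) in enumerate(dihedrals):
            dih_ph0[t, s] = _dihedral(pos_by_state[s], *ijkl)

    # ring for the topology audit: hinge -> armL -> kleisin arc -> armR
    ring = np.concatenate([
        np.arange(aul, aul + n_arm),            # hinge attach -> elbow L
        np.arange(all_, all_ + n_arm),          # elbow -> head L
        np.arange(klo + 13, klo - 1, -1),       # kleisin arc L end -> R end
        np.arange(alr + n_arm - 1, alr - 1, -1),  # head R -> elbow R
        np.arange(aur + n_arm - 1, aur - 1, -1),  # elbow -> hinge attach R
        np.arange(up_row + 7, up_row - 1, -1),  # across the hinge plate
    ])

    return SMCCGeometry(
        variant=variant,
        state_index=state_index,
        positions=pos_by_state[state_index].copy(),
        positions_by_state=pos_by_state,
        body_id=body_id,
        bead_class=bead_class,
        bead_mass=mass,
        top_att=top_att, mid_att=mid_att, bot_att=bot_att,
        anchor_bead=anchor_bead,
        bonds=bond_arr, bond_r0=bond_r0,
        angles=ang_arr, angle_kappa=ang_kappa,
        angle_theta0_by_state=ang_th0, angle_labels=ang_labels,
        dihedrals=dih_arr, dihedral_kappa=dih_kappa,
        dihedral_phi0_by_state=dih_ph0, dihedral_labels=dih_labels,
        ring=ring,
        calibration={
            "arm_open_angle_deg": skels[1]["arm_open_deg"],
            "arm_closed_angle_deg": skels[0]["arm_open_deg"],
            "hinge_height_open_nm": skels[1]["hinge_z"],
            "hinge_height_closed_nm": skels[0]["hinge_z"],
            "fold_deg_by_state": [skels[s]["fold_deg"] for s in range(3)],
            "arm_beads_per_segment": n_arm,
        },
    )


def upper_aperture(geom: SMCCGeometry, state_index: int) -> float:
    """Narrowest left-arm/right-arm bead-centre gap above the bridge.

    A 3.5-nm DNA chain fits through the gap when it exceeds twice the
    protein-DNA contact distance (5 nm); the spare width beyond that is
    the clearance.
    """
    p = geom.positions_by_state[state_index]
    left = np.concatenate([geom.body_indices(ARM_UL), geom.body_indices(ARM_LL)])
    right = np.concatenate([geom.body_indices(ARM_UR), geom.body_indices(ARM_LR)])
    d = np.linalg.norm(p[left][:, None, :] - p[right][None, :, :], axis=2)
    return float(d.min())


# --------------------------------------------------------------------------
# threaded initial configurations
# --------------------------------------------------------------------------

def _bottom_binding_line(geom: SMCCGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Point and direction of the DNA line bound at the apo bottom site."""
    p = geom.positions_by_state[0]
    centroid = p[geom.bot_att].mean(axis=0)
    # place the DNA axis one contact distance towards the compartment
    # interior (the kleisin arc centre), perpendicular to x
    centre = p[geom.body_indices(KLEISIN)].mean(axis=0)
    inward = centre - centroid
    inward[0] = 0.0
    inward /= np.linalg.norm(inward)
    return centroid + ff.PD_DIAMETER * inward, np.array([1.0, 0.0, 0.0])


def _arc_through(p0: np.ndarray, p1: np.ndarray, arc_len: float,
                 bulge: np.ndarray, n_beads: int) -> np.ndarray:
    """Cell-centred beads along a circular arc from p0 to p1.

    The arc has total length ``arc_len`` (>= chord), lies in the plane
    spanned by the chord and ``bulge``, and bulges towards ``bulge``.
    Used to park slack DNA contour (loops and fixed-endpoint detours)
    without clashes.
    """
    chord_v = p1 - p0
    chord = float(np.linalg.norm(chord_v))
    if arc_len < chord * 1.0000001:
        t = (np.arange(n_beads) + 0.5) / n_beads
        return p0[None, :] + t[:, None] * chord_v[None, :]

    # solve arc angle theta from  chord/arc_len = sin(theta/2)/(theta/2)
    from scipy.optimize import brentq
    ratio = chord / arc_len

    def f(theta):
        return math.sin(theta / 2.0) / (theta / 2.0) - ratio

    theta = brentq(f, 1e-6, 2.0 * math.pi - 1e-9)
    radius = arc_len / theta
    e_c = chord_v / chord
    e_p = bulge - np.dot(bulge, e_c) * e_c  # in-plane, perp to chord
    e_p = e_p / np.linalg.norm(e_p)
    mid = 0.5 * (p0 + p1)
    centre = mid - radius * math.cos(theta / 2.0) * e_p
    # endpoints sit at +/- theta/2 about the bulge axis; sweep from p0's
    # angle through 0 (the bulge extreme) to p1's
    v0 = p0 - centre
    a0 = math.atan2(np.dot(v0, e_c), np.dot(v0, e_p))
    tt = (np.arange(n_beads) + 0.5) / n_beads
    ang = a0 * (1.0 - 2.0 * tt)
    pts = (centre[None, :]
           + radius * np.cos(ang)[:, None] * e_p[None, :]
           + radius * np.sin(ang)[:, None] * e_c[None, :])
    return pts


def thread_translocation_config(dna: DNAPolymer, smcc: SMCCGeometry,
                                relax: bool = True):
    """Thread straight DNA through the apo SMCC lower compartment.

    DNA passes through the kleisin compartment along x with its midpoint
    bead at the bottom binding site.  Returns an assembled
    :class:`~smcsim.system.SystemState`.
    """
    from . import system as sysmod

    if smcc.state_index != 0:
        raise InvalidParameterError("threading requires the SMCC in the apo state")
    n = dna.n_beads
    point, direction = _bottom_binding_line(smcc)
    mid = (n - 1) // 2
    x = (np.arange(n) - mid) * dna.params.bond_length
    pos = point[None, :] + x[:, None] * direction[None, :]
    polymer = DNAPolymer(dna.params, pos)
    state = sysmod.assemble_system(polymer, smcc, smcc_state_index=0)
    if relax:
        sysmod.relax(state)
    return state


def thread_extrusion_config(dna: DNAPolymer, smcc: SMCCGeometry,
                            initial_loop_bp: int = 400,
                            relax: bool = True):
    """Thread DNA with a safety-belt anchor and an initial slack loop.

    One DNA bead is bonded to the kleisin exterior anchor bead; a slack
    loop of ``initial_loop_bp`` lies between the anchor and the
    bottom-site contact.  The motor steps towards decreasing bead index,
    so the anchor sits ``initial_loop_bp/5`` beads *above* the position
    bead and the loop grows as the SMCC translocates.
    """
    from . import system as sysmod

    if smcc.state_index != 0:
        raise InvalidParameterError("threading requires the SMCC in the apo state")
    bpb = dna.params.bp_per_bead
    if initial_loop_bp % (bpb) != 0 or initial_loop_bp < 0:
        raise InvalidParameterError("initial loop must be a non-negative "
                                    f"multiple of {bpb} bp")
    loop_beads = initial_loop_bp // bpb
    n = dna.n_beads
    b = dna.params.bond_length
    i_pos = (n - 1) // 2 - loop_beads // 2
    i_anchor = i_pos + max(loop_beads, 1)
    if i_pos < 2 or i_anchor > n - 3:
        raise InvalidParameterError("initial loop too large for the molecule")

    point, direction = _bottom_binding_line(smcc)
    pos = np.empty((n, 3))
    if loop_beads == 0:
        # degenerate loop: DNA stays straight; the anchor bond (formed at
        # assembly) pulls the adjacent bead towards the kleisin exterior
        x = (np.arange(n) - i_pos) * b
        pos[:] = point[None, :] + x[:, None] * direction[None, :]
    else:
        anchor_prot = smcc.positions_by_state[0][smcc.anchor_bead]
        kle_centre = smcc.positions_by_state[0][
            smcc.body_indices(KLEISIN)].mean(axis=0)
        out = anchor_prot - kle_centre
        out /= np.linalg.norm(out)
        anchor_pos = anchor_prot + 2.0 * out
        # track ahead of the motor: straight line towards -x
        idx_fwd = np.arange(0, i_pos + 1)
        pos[idx_fwd] = (point[None, :]
                        + ((idx_fwd - i_pos) * b)[:, None] * direction)
        # the loop exits the pocket behind the motor (a straight stub
        # through the ring towards +x), then curls around the outside of
        # the complex back to the exterior anchor: one ring passage
        stub = min(10, loop_beads - 2)
        idx_stub = np.arange(i_pos + 1, i_pos + stub + 1)
        pos[idx_stub] = (point[None, :]
                         + ((idx_stub - i_pos) * b)[:, None] * direction)
        n_arc = loop_beads - stub - 1
        if n_arc > 0:
            s_end = point + (stub + 1) * b * direction
            arc = _arc_through(s_end, anchor_pos, (n_arc + 1) * b,
                               np.array([-0.2, -1.0, -0.6]), n_arc)
            pos[i_pos + stub + 1:i_anchor] = arc
        pos[i_anchor] = anchor_pos
        # far side: straight line away from the anchor towards +x
        idx_far = np.arange(i_anchor + 1, n)
        pos[idx_far] = (anchor_pos[None, :]
                        + ((idx_far - i_anchor) * b)[:, None] * direction)
    polymer = DNAPolymer(dna.params, pos)
    state = sysmod.assemble_system(polymer, smcc, smcc_state_index=0,
                                   dna_anchor_bead=i_anchor)
    if relax:
        sysmod.relax(state)
    return state
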