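"""Observables: position on DNA, captured segments, loops, step statistics.

This module turns raw :class:`~smcsim.system.SystemState` snapshots and
per-cycle records into the quantities of interest for an SMC motor:

* the motor *position* along DNA (the bead nearest the bottom binding
  site) and per-cycle step sizes,
* the *captured DNA segment* in the ATP-bound state, with its 1a/1b
  substate (DNA held near the compartment centre vs. at the top site),
* extruded *loop* sizes for safety-belt runs,
* worm-like-chain force/extension conversions (Marko-Siggia
  interpolation),
* Gaussian-mixture fits of step/segment distributions with an
  AICc-based one-vs-two-peak verdict,
* the ring-threading topology audit,
* rescaling of the simulation clock to experimental seconds via the
  calibrated ATPase cycle duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .units import KT_PN_NM

#: experimental time calibration: one ATPase cycle in seconds
CYCLE_DURATION_S = 0.13
#: conversion between mean step (nm) and velocity (kbp/s)
STEP_NM_PER_KBP_S = 44.2


class InvalidStateError(RuntimeError):
    pass


class OutOfRangeError(ValueError):
    pass


# --------------------------------------------------------------------------
# position / segment / loop measurements on a SystemState
# --------------------------------------------------------------------------

def smcc_position_on_dna(state) -> int:
    """Index of the DNA bead nearest the bottom-site attractive centroid.

    Ties resolve to the lower index (argmin convention).
    """
    centroid = state.pos[state.bot_att].mean(axis=0)
    d = np.linalg.norm(state.pos[:state.n_dna] - centroid, axis=1)
    return int(np.argmin(d))


def upper_compartment_com(state) -> np.ndarray:
    """Centroid of arm + hinge + bridge beads (the upper compartment)."""
    sel = (state.body_of >= 0) & (state.body_of != 6)  # all but the kleisin
    return state.pos[sel].mean(axis=0)


def detect_captured_segment(state) -> tuple[str, float]:
    """(substate, segment length in nm) for the ATP-bound state.

    The DNA bead closest to the upper-compartment centre of mass and the
    one closest to the top binding site are located; the smaller of the
    two distances decides the substate (1b when the top site wins).  The
    captured segment is the contour distance from the position bead to
    that smallest-proximity bead.
    """
    if state.smcc_state_index != 1:
        raise InvalidStateError("captured-segment detection requires state 1")
    dna = state.pos[:state.n_dna]
    com = upper_compartment_com(state)
    top = state.pos[state.top_att].mean(axis=0)
    d_com = np.linalg.norm(dna - com, axis=1)
    d_top = np.linalg.norm(dna - top, axis=1)
    i_com, i_top = int(np.argmin(d_com)), int(np.argmin(d_top))
    if d_top[i_top] < d_com[i_com]:
        substate, far = "1b", i_top
    else:
        substate, far = "1a", i_com
    i_pos = smcc_position_on_dna(state)
    seg = abs(far - i_pos) * state.dna.params.bond_length
    return substate, seg


def measure_loop_beads(state) -> int:
    """Bead intervals between the safety-belt anchor and the position bead."""
    if state.dna_anchor_bead < 0:
        raise InvalidStateError("no safety-belt anchor in this system")
    i_pos = smcc_position_on_dna(state)
    return abs(state.dna_anchor_bead - i_pos)


def extruded_loop_size(records) -> pd.DataFrame:
    """Per-cycle extruded-loop trace (bp and nm) from cycle records."""
    rows = []
    for r in records:
        if r.loop_bp is None:
            raise InvalidStateError("records carry no loop observable")
        rows.append((r.cycle, r.loop_bp, r.loop_nm))
    return pd.DataFrame(rows, columns=["cycle", "loop_bp", "loop_nm"])


# --------------------------------------------------------------------------
# worm-like chain
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WLCModel:
    """Marko-Siggia interpolation for a worm-like chain."""

    persistence_length: float = 50.0  # nm
    kT_pN_nm: float = KT_PN_NM

    def force_pn(self, x: float) -> float:
        """Tension (pN) at relative extension ``x`` in [0, 1)."""
        if not 0.0 <= x < 1.0:
            raise OutOfRangeError("relative extension must be in [0, 1)")
        fl = 1.0 / (4.0 * (1.0 - x) ** 2) - 0.25 + x
        return self.kT_pN_nm / self.persistence_length * fl

    def extension(self, f_pn: float) -> float:
        """Relative extension at tension ``f_pn`` >= 0 (monotone inverse)."""
        if f_pn < 0:
            raise OutOfRangeError("tension must be non-negative")
        if f_pn == 0.0:
            return 0.0
        return brentq(lambda x: self.force_pn(x) - f_pn, 0.0, 1.0 - 1e-12,
                      xtol=1e-12, rtol=1e-14)


def wlc_force_from_extension(x: float, model: WLCModel = WLCModel()) -> float:
    return model.force_pn(x)


def wlc_extension_from_force(f_pn: float, model: WLCModel = WLCModel()) -> float:
    return model.extension(f_pn)


# --------------------------------------------------------------------------
# step-size distributions and mixture fits
# --------------------------------------------------------------------------

@dataclass
class StepDistribution:
    """Samples (nm) plus fitted mixture description."""

    samples: np.ndarray
    n_components: int = 0
    means: np.ndarray = None
    sds: np.ndarray = None
    weights: np.ndarray = None
    aicc: dict = None

    def histogram(self, bins: int = 30):
        density, edges = np.histogram(self.samples, bins=bins, density=True)
        return density, edges


class FitFailure(RuntimeError):
    pass


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = 2.0 * k - 2.0 * loglik
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_step_mixture(samples, seed: int = 0) -> StepDistribution:
    """Fit 1- and 2-component Gaussian mixtures; pick by small-sample AICc.

    For a two-peak verdict, component 0 is the smaller-mean peak (the
    power-stroke / "1a" mode) and component 1 the larger (segment
    capture at the top site, "1b").
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(samples, dtype=float).reshape(-1, 1)
    n = x.shape[0]
    if n < 30:
        raise FitFailure("need at least 30 samples for a mixture verdict")
    if np.std(x) < 1e-12:
        raise FitFailure("degenerate (zero-variance) samples")
    fits, aiccs = {}, {}
    for ncomp, k in ((1, 2), (2, 5)):
        gm = GaussianMixture(n_components=ncomp, n_init=3, random_state=seed)
        gm.fit(x)
        fits[ncomp] = gm
        aiccs[ncomp] = _aicc(gm.score(x) * n, k, n)
    best = 1 if aiccs[1] <= aiccs[2] else 2
    gm = fits[best]
    order = np.argsort(gm.means_.ravel())
    return StepDistribution(
        samples=x.ravel(),
        n_components=best,
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        weights=gm.weights_.ravel()[order],
        aicc={1: aiccs[1], 2: aiccs[2]},
    )


# --------------------------------------------------------------------------
# time calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeCalibration:
    """Mapping of ATPase cycles to experimental seconds."""

    cycle_duration_s: float = CYCLE_DURATION_S
    step_nm_per_kbp_s: float = STEP_NM_PER_KBP_S

    def velocity_kbp_s(self, step_nm: float) -> float:
        return step_nm / self.step_nm_per_kbp_s


def rescale_time(records, calibration: TimeCalibration = TimeCalibration()
                 ) -> pd.DataFrame:
    """Attach wall-clock timestamps and velocities to cycle records."""
    rows = []
    for r in records:
        rows.append({
            "cycle": r.cycle,
            "time_s": (r.cycle + 1) * calibration.cycle_duration_s,
            "step_nm": r.step_nm,
            "velocity_kbp_s": calibration.velocity_kbp_s(r.step_nm)
            if r.step_nm is not None else np.nan,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# topology audit
# --------------------------------------------------------------------------

@dataclass
class TopologyStatus:
    ring_threaded: bool
    compartment: str  # upper | lower | both | none
    crossings: int


def _segment_triangle_hits(p0, p1, a, b, c):
    """Vectorized segment/triangle intersection (Moller-Trumbore).

    p0, p1: (m,3) segment endpoints; a,b,c: single triangle vertices.
    Returns boolean mask and intersection points.
    """
    d = p1 - p0
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = h @ e1
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = p0 - a
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = np.einsum("ij,ij->i", q, d) * inv
    t = (q @ e2) * inv
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t >= 0) & (t < 1)
    pts = p0 + t[:, None] * d
    return hit, pts


def topology_check(state) -> TopologyStatus:
    """Does the DNA pierce the arm-arm-kleisin ring, and where?

    The ring polygon (ordered protein beads around the tripartite ring)
    is triangulated as a fan about its centroid; crossings of the DNA
    polyline through that spanning surface are counted.  An odd count
    means the DNA is threaded.  Each crossing is classified as above or
    below the ATPase-head line to report the occupied compartment(s).
    """
    ring = state.pos[state.ring]
    gaps = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)
    if gaps.max() > 3.0 * 3.5:
        raise InvalidStateError("ring not geometrically closed")
    # fan apex at the kleisin-pocket centre: the DNA pierces the spanning
    # surface steeply there, which keeps the crossing count robust even
    # when the tripartite ring is strongly non-planar (folded states)
    centroid = state.pos[state.body_of == 6].mean(axis=0)
    dna = state.pos[:state.n_dna]
    p0, p1 = dna[:-1], dna[1:]
    # collect crossing points per DNA segment; a segment grazing a shared
    # edge of two fan triangles registers in both, so coincident points
    # on the same segment are collapsed before counting parity
    seg_hits: dict[int, list[np.ndarray]] = {}
    nring = ring.shape[0]
    for k in range(nring):
        a, b = ring[k], ring[(k + 1) % nring]
        hit, pts = _segment_triangle_hits(p0, p1, a, b, centroid)
        for i in np.nonzero(hit)[0]:
            seg_hits.setdefault(int(i), []).append(pts[i])
    crossings = 0
    points = []
    for i, plist in seg_hits.items():
        kept: list[np.ndarray] = []
        for p in plist:
            if all(np.linalg.norm(p - q) > 1e-7 for q in kept):
                kept.append(p)
        crossings += len(kept)
        points.extend(kept)
    threaded = crossings % 2 == 1
    compartment = "none"
    if points:
        pts = np.vstack(points)
        bridge_centroid = state.pos[state.body_of == 5].mean(axis=0)
        up = state.pos[state.top_att].mean(axis=0) - bridge_centroid
        up /= np.linalg.norm(up)
        side = (pts - bridge_centroid) @ up
        has_up = bool((side > 0).any())
        has_dn = bool((side <= 0).any())
        compartment = ("both" if has_up and has_dn
                       else "upper" if has_up else "lower")
    return TopologyStatus(ring_threaded=threaded, compartment=compartment,
                          crossings=crossings)
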