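"""Numba-compiled inner loops: forces, neighbour list, Langevin stepping.

Everything here operates on plain numpy arrays owned by
:class:`smcsim.system.SystemState`.  The integrator is velocity-Verlet
with a per-bead Langevin thermostat (friction + unit-variance uniform
random kicks, as in standard MD practice); rigid bodies aggregate their
beads' forces into a net force and torque and are propagated with a
quaternion update.  Per-bead friction applied at the bead velocity
``v_com + omega x r`` yields consistent translational and rotational
friction/noise for the bodies.

Pair interactions exist only between DNA beads and anything else
(DNA-DNA excluded volume and DNA-protein terms); protein-protein
interactions are handled by the bonded couplings and body rigidity.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# force magnitude cap (kBT/nm) guarding LJ cores during clashes/ramps:
# far above every physical force scale in the model (site binding ~10,
# tension < 1, bending < 5 kBT/nm) but low enough that transient deep
# overlaps cannot inject destabilizing kinetic energy
FORCE_CAP = 100.0

_SQRT3 = 1.7320508075688772


# --------------------------------------------------------------------------
# RNG: splitmix64 -> uniform with unit variance
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _next_u64(state):
    state[0] = (state[0] + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state[0]
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _rand_unitvar(state):
    """Uniform random number with zero mean and unit variance."""
    u = _next_u64(state)
    return _SQRT3 * (2.0 * (np.float64(u) * 5.421010862427522e-20) - 1.0)


# --------------------------------------------------------------------------
# neighbour list
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy")
def build_neighbor_list(pos, bead_class, n_dna, rlist2, excl_a, excl_b,
                        nl_i, nl_j):
    """All DNA-involving pairs within the per-class list radius.

    Returns the pair count, or -1 on overflow.  DNA beads are indices
    0..n_dna-1; first-/second-neighbour DNA pairs are excluded (bonded
    and angle-coupled), as is the safety-belt anchor pair.
    """
    n = pos.shape[0]
    cap = nl_i.shape[0]
    count = 0
    # bounding sphere of the protein beads prunes the DNA x protein block
    have_prot = n > n_dna
    cx = cy = cz = 0.0
    prad = 0.0
    if have_prot:
        for j in range(n_dna, n):
            cx += pos[j, 0]
            cy += pos[j, 1]
            cz += pos[j, 2]
        m = n - n_dna
        cx /= m
        cy /= m
        cz /= m
        for j in range(n_dna, n):
            dx = pos[j, 0] - cx
            dy = pos[j, 1] - cy
            dz = pos[j, 2] - cz
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > prad:
                prad = r2
        rmax = 0.0
        for c in range(1, rlist2.shape[0]):
            if rlist2[c] > rmax:
                rmax = rlist2[c]
        prune2 = (np.sqrt(prad) + np.sqrt(rmax)) ** 2
    else:
        prune2 = 0.0
    rl_dna = rlist2[0]
    for i in range(n_dna):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(i + 3, n_dna):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rl_dna:
                if count >= cap:
                    return -1
                nl_i[count] = i
                nl_j[count] = j
                count += 1
        if not have_prot:
            continue
        dx = cx - xi
        dy = cy - yi
        dz = cz - zi
        if dx * dx + dy * dy + dz * dz > prune2:
            continue
        for j in range(n_dna, n):
            if i == excl_a and j == excl_b:
                continue
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rlist2[bead_class[j]]:
                if count >= cap:
                    return -1
                nl_i[count] = i
                nl_j[count] = j
                count += 1
    return count


# --------------------------------------------------------------------------
# forces and energy
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy")
def compute_forces(pos, f,
                   bond_ij, bond_kind, bond_k, bond_r0, bond_rmax,
                   ang_ijk, ang_kappa, ang_th0,
                   dih_ijkl, dih_kappa, dih_phi0,
                   bead_class, n_dna, peps_rep, peps_att, psig2, prc2,
                   pshift, nl_i, nl_j, n_pairs, fext):
    """Fill ``f`` with conservative forces.  Returns 0, or 1 on a
    non-finite/singular geometry (diagnostic for integration blowup)."""
    n = pos.shape[0]
    bad = 0
    for i in range(n):
        f[i, 0] = fext[i, 0]
        f[i, 1] = fext[i, 1]
        f[i, 2] = fext[i, 2]

    # fused DNA chain pass: consecutive bonds share tangent vectors with
    # the bending angles (DNA terms are the leading entries of the
    # bond/angle tables)
    n_chain_bonds = n_dna - 1 if n_dna >= 2 else 0
    n_chain_angles = n_dna - 2 if n_dna >= 3 else 0
    ptx = pty = ptz = 0.0
    pinv = 0.0
    for k in range(n_chain_bonds):
        tx = pos[k + 1, 0] - pos[k, 0]
        ty = pos[k + 1, 1] - pos[k, 1]
        tz = pos[k + 1, 2] - pos[k, 2]
        r2 = tx * tx + ty * ty + tz * tz
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        dr = r - bond_r0[k]
        x2 = (dr / bond_rmax[k]) ** 2
        if x2 >= 0.9999:
            x2 = 0.9999
            bad = 1
        fr = -bond_k[k] * dr / (1.0 - x2)
        if fr > FORCE_CAP:
            fr = FORCE_CAP
        elif fr < -FORCE_CAP:
            fr = -FORCE_CAP
        frr = fr * inv_r
        f[k + 1, 0] += frr * tx
        f[k + 1, 1] += frr * ty
        f[k + 1, 2] += frr * tz
        f[k, 0] -= frr * tx
        f[k, 1] -= frr * ty
        f[k, 2] -= frr * tz
        if k >= 1 and k - 1 < n_chain_angles:
            # angle at bead k between beads k-1, k, k+1
            kap = ang_kappa[k - 1]
            cs = -(ptx * tx + pty * ty + ptz * tz) * pinv * inv_r
            if cs > 1.0:
                cs = 1.0
            elif cs < -1.0:
                cs = -1.0
            theta = np.arccos(cs)
            sn = np.sqrt(1.0 - cs * cs)
            if sn < 1e-6:
                sn = 1e-6
            coef = -kap * (theta - ang_th0[k - 1])
            iux, iuy, iuz = -ptx * pinv, -pty * pinv, -ptz * pinv
            ivx, ivy, ivz = tx * inv_r, ty * inv_r, tz * inv_r
            ci = coef * pinv / sn
            ck = coef * inv_r / sn
            fx_i = ci * (cs * iux - ivx)
            fy_i = ci * (cs * iuy - ivy)
            fz_i = ci * (cs * iuz - ivz)
            fx_k = ck * (cs * ivx - iux)
            fy_k = ck * (cs * ivy - iuy)
            fz_k = ck * (cs * ivz - iuz)
            f[k - 1, 0] += fx_i
            f[k - 1, 1] += fy_i
            f[k - 1, 2] += fz_i
            f[k + 1, 0] += fx_k
            f[k + 1, 1] += fy_k
            f[k + 1, 2] += fz_k
            f[k, 0] -= fx_i + fx_k
            f[k, 1] -= fy_i + fy_k
            f[k, 2] -= fz_i + fz_k
        ptx, pty, ptz = tx, ty, tz
        pinv = inv_r

    # remaining bonds (SMCC inter-body couplings, safety belt)
    for b in range(n_chain_bonds, bond_ij.shape[0]):
        if bond_k[b] == 0.0:
            continue
        i = bond_ij[b, 0]
        j = bond_ij[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            bad = 1
            continue
        dr = r - bond_r0[b]
        if bond_kind[b] == 1:
            x2 = (dr / bond_rmax[b]) ** 2
            if x2 >= 0.9999:
                x2 = 0.9999
                bad = 1
            fr = -bond_k[b] * dr / (1.0 - x2)
        else:
            fr = -bond_k[b] * dr
        if fr > FORCE_CAP:
            fr = FORCE_CAP
        elif fr < -FORCE_CAP:
            fr = -FORCE_CAP
        frr = fr / r
        fx = frr * dx
        fy = frr * dy
        fz = frr * dz
        f[j, 0] += fx
        f[j, 1] += fy
        f[j, 2] += fz
        f[i, 0] -= fx
        f[i, 1] -= fy
        f[i, 2] -= fz

    # remaining angles (SMCC)
    for a in range(n_chain_angles, ang_ijk.shape[0]):
        kap = ang_kappa[a]
        if kap == 0.0:
            continue
        i = ang_ijk[a, 0]
        j = ang_ijk[a, 1]
        k = ang_ijk[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ru2 = ux * ux + uy * uy + uz * uz
        rv2 = vx * vx + vy * vy + vz * vz
        if ru2 < 1e-24 or rv2 < 1e-24:
            bad = 1
            continue
        inv_ru = 1.0 / np.sqrt(ru2)
        inv_rv = 1.0 / np.sqrt(rv2)
        cs = (ux * vx + uy * vy + uz * vz) * inv_ru * inv_rv
        if cs > 1.0:
            cs = 1.0
        elif cs < -1.0:
            cs = -1.0
        theta = np.arccos(cs)
        sn = np.sqrt(1.0 - cs * cs)
        if sn < 1e-6:
            sn = 1e-6
        coef = -kap * (theta - ang_th0[a])  # = -dU/dtheta
        # dtheta/dri = (cos*u_hat - v_hat) / (ru * sin)
        iux, iuy, iuz = ux * inv_ru, uy * inv_ru, uz * inv_ru
        ivx, ivy, ivz = vx * inv_rv, vy * inv_rv, vz * inv_rv
        ci = coef * inv_ru / sn
        ck = coef * inv_rv / sn
        fx_i = ci * (cs * iux - ivx)
        fy_i = ci * (cs * iuy - ivy)
        fz_i = ci * (cs * iuz - ivz)
        fx_k = ck * (cs * ivx - iux)
        fy_k = ck * (cs * ivy - iuy)
        fz_k = ck * (cs * ivz - iuz)
        f[i, 0] += fx_i
        f[i, 1] += fy_i
        f[i, 2] += fz_i
        f[k, 0] += fx_k
        f[k, 1] += fy_k
        f[k, 2] += fz_k
        f[j, 0] -= fx_i + fx_k
        f[j, 1] -= fy_i + fy_k
        f[j, 2] -= fz_i + fz_k

    # dihedrals
    for d in range(dih_ijkl.shape[0]):
        kap = dih_kappa[d]
        if kap == 0.0:
            continue
        i = dih_ijkl[d, 0]
        j = dih_ijkl[d, 1]
        k = dih_ijkl[d, 2]
        l = dih_ijkl[d, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-12 or n2sq < 1e-12 or b2n < 1e-12:
            continue
        # phi = atan2((n1 x n2).b2hat, n1.n2)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        sphi = (cxx * b2x + cxy * b2y + cxz * b2z) / b2n
        cphi = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sphi, cphi)
        dphi = phi - dih_phi0[d]
        while dphi > np.pi:
            dphi -= 2.0 * np.pi
        while dphi < -np.pi:
            dphi += 2.0 * np.pi
        coef = -kap * dphi  # = -dU/dphi
        # dphi/dr1 = -(|b2|/n1sq) n1 ; dphi/dr4 = (|b2|/n2sq) n2
        t1x = -(b2n / n1sq) * n1x
        t1y = -(b2n / n1sq) * n1y
        t1z = -(b2n / n1sq) * n1z
        t4x = (b2n / n2sq) * n2x
        t4y = (b2n / n2sq) * n2y
        t4z = (b2n / n2sq) * n2z
        d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        t2x = -(1.0 + d12) * t1x + d32 * t4x
        t2y = -(1.0 + d12) * t1y + d32 * t4y
        t2z = -(1.0 + d12) * t1z + d32 * t4z
        t3x = d12 * t1x - (1.0 + d32) * t4x
        t3y = d12 * t1y - (1.0 + d32) * t4y
        t3z = d12 * t1z - (1.0 + d32) * t4z
        f[i, 0] += coef * t1x
        f[i, 1] += coef * t1y
        f[i, 2] += coef * t1z
        f[j, 0] += coef * t2x
        f[j, 1] += coef * t2y
        f[j, 2] += coef * t2z
        f[k, 0] += coef * t3x
        f[k, 1] += coef * t3y
        f[k, 2] += coef * t3z
        f[l, 0] += coef * t4x
        f[l, 1] += coef * t4y
        f[l, 2] += coef * t4z

    # pairs: WCA core (strength eps_rep) + attractive tail (eps_att);
    # with eps_rep == eps_att this is exactly truncated-shifted LJ
    for p in range(n_pairs):
        i = nl_i[p]
        j = nl_j[p]
        cls = 0 if j < n_dna else bead_class[j]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= prc2[cls]:
            continue
        sig2 = psig2[cls]
        if r2 < 1.2599210498948732 * sig2:
            eps = peps_rep[cls]
        else:
            eps = peps_att[cls]
        if eps == 0.0:
            continue
        if r2 < 1e-12:
            bad = 1
            continue
        inv_r2 = 1.0 / r2
        sr2 = sig2 * inv_r2
        sr6 = sr2 * sr2 * sr2
        fr_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv_r2
        fmag2 = fr_over_r * fr_over_r * r2
        if fmag2 > FORCE_CAP * FORCE_CAP:
            fr_over_r = FORCE_CAP / np.sqrt(r2)
        fx = fr_over_r * dx
        fy = fr_over_r * dy
        fz = fr_over_r * dz
        f[j, 0] += fx
        f[j, 1] += fy
        f[j, 2] += fz
        f[i, 0] -= fx
        f[i, 1] -= fy
        f[i, 2] -= fz
    return bad


@njit(cache=True, fastmath=True, error_model="numpy")
def compute_energy(pos,
                   bond_ij, bond_kind, bond_k, bond_r0, bond_rmax,
                   ang_ijk, ang_kappa, ang_th0,
                   dih_ijkl, dih_kappa, dih_phi0,
                   bead_class, n_dna, peps_rep, peps_att, psig2, prc2,
                   pshift, nl_i, nl_j, n_pairs):
    """Total potential energy, consistent with :func:`compute_forces`
    (without the force cap, so valid away from hard overlaps)."""
    e = 0.0
    for b in range(bond_ij.shape[0]):
        if bond_k[b] == 0.0:
            continue
        i = bond_ij[b, 0]
        j = bond_ij[b, 1]
        d = pos[j] - pos[i]
        r = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        dr = r - bond_r0[b]
        if bond_kind[b] == 1:
            x2 = (dr / bond_rmax[b]) ** 2
            if x2 >= 1.0:
                return np.inf
            e += -0.5 * bond_k[b] * bond_rmax[b] ** 2 * np.log(1.0 - x2)
        else:
            e += 0.5 * bond_k[b] * dr * dr
    for a in range(ang_ijk.shape[0]):
        if ang_kappa[a] == 0.0:
            continue
        i, j, k = ang_ijk[a, 0], ang_ijk[a, 1], ang_ijk[a, 2]
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        ru = np.sqrt(u[0] * u[0] + u[1] * u[1] + u[2] * u[2])
        rv = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
        cs = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (ru * rv)
        if cs > 1.0:
            cs = 1.0
        elif cs < -1.0:
            cs = -1.0
        dth = np.arccos(cs) - ang_th0[a]
        e += 0.5 * ang_kappa[a] * dth * dth
    for d0 in range(dih_ijkl.shape[0]):
        if dih_kappa[d0] == 0.0:
            continue
        i, j, k, l = dih_ijkl[d0, 0], dih_ijkl[d0, 1], dih_ijkl[d0, 2], dih_ijkl[d0, 3]
        b1 = pos[j] - pos[i]
        b2 = pos[k] - pos[j]
        b3 = pos[l] - pos[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.sqrt(b2[0] * b2[0] + b2[1] * b2[1] + b2[2] * b2[2])
        sphi = np.dot(np.cross(n1, n2), b2) / b2n
        cphi = np.dot(n1, n2)
        dphi = np.arctan2(sphi, cphi) - dih_phi0[d0]
        while dphi > np.pi:
            dphi -= 2.0 * np.pi
        while dphi < -np.pi:
            dphi += 2.0 * np.pi
        e += 0.5 * dih_kappa[d0] * dphi * dphi
    for p in range(n_pairs):
        i = nl_i[p]
        j = nl_j[p]
        cls = 0 if j < n_dna else bead_class[j]
        d = pos[j] - pos[i]
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        if r2 >= prc2[cls]:
            continue
        sig2 = psig2[cls]
        sr2 = sig2 / r2
        sr6 = sr2 * sr2 * sr2
        u = sr6 * sr6 - sr6
        if r2 < 1.2599210498948732 * sig2:
            # inside the WCA core: eps_rep*(4u+1) + eps_att*(-1 - S)
            e += peps_rep[cls] * (4.0 * u + 1.0) \
                + peps_att[cls] * (-1.0 - pshift[cls])
        else:
            e += peps_att[cls] * (4.0 * u - pshift[cls])
    return e


# --------------------------------------------------------------------------
# rigid-body helpers
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _quat_to_rot(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True, fastmath=True, error_model="numpy")
def _body_kinematics(nb, bquat, binert, bang, Rbuf, omega):
    """omega = R I^-1 R^T L for every body; Rbuf filled as a side effect."""
    for b in range(nb):
        R = Rbuf[b]
        _quat_to_rot(bquat[b], R)
        lx, ly, lz = bang[b, 0], bang[b, 1], bang[b, 2]
        # body-frame L
        blx = R[0, 0] * lx + R[1, 0] * ly + R[2, 0] * lz
        bly = R[0, 1] * lx + R[1, 1] * ly + R[2, 1] * lz
        blz = R[0, 2] * lx + R[1, 2] * ly + R[2, 2] * lz
        ox = blx / binert[b, 0]
        oy = bly / binert[b, 1]
        oz = blz / binert[b, 2]
        omega[b, 0] = R[0, 0] * ox + R[0, 1] * oy + R[0, 2] * oz
        omega[b, 1] = R[1, 0] * ox + R[1, 1] * oy + R[1, 2] * oz
        omega[b, 2] = R[2, 0] * ox + R[2, 1] * oy + R[2, 2] * oz


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _omega_of(q, L, Ib, R):
    """Space-frame angular velocity from space-frame L at orientation q."""
    _quat_to_rot(q, R)
    lx, ly, lz = L[0], L[1], L[2]
    blx = R[0, 0] * lx + R[1, 0] * ly + R[2, 0] * lz
    bly = R[0, 1] * lx + R[1, 1] * ly + R[2, 1] * lz
    blz = R[0, 2] * lx + R[1, 2] * ly + R[2, 2] * lz
    ox = blx / Ib[0]
    oy = bly / Ib[1]
    oz = blz / Ib[2]
    wx = R[0, 0] * ox + R[0, 1] * oy + R[0, 2] * oz
    wy = R[1, 0] * ox + R[1, 1] * oy + R[1, 2] * oz
    wz = R[2, 0] * ox + R[2, 1] * oy + R[2, 2] * oz
    return wx, wy, wz


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _quat_step(q, wx, wy, wz, h, out):
    w, x, y, z = q[0], q[1], q[2], q[3]
    out[0] = w + h * 0.5 * (-wx * x - wy * y - wz * z)
    out[1] = x + h * 0.5 * (wx * w + wy * z - wz * y)
    out[2] = y + h * 0.5 * (wy * w + wz * x - wx * z)
    out[3] = z + h * 0.5 * (wz * w + wx * y - wy * x)
    norm = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
    out[0] /= norm
    out[1] /= norm
    out[2] /= norm
    out[3] /= norm


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _richardson_rotate(q, L, Ib, R, dt):
    """Time-reversible midpoint (Richardson) quaternion update."""
    qh = np.empty(4)
    wx, wy, wz = _omega_of(q, L, Ib, R)
    _quat_step(q, wx, wy, wz, 0.5 * dt, qh)
    wx, wy, wz = _omega_of(qh, L, Ib, R)
    _quat_step(q, wx, wy, wz, dt, qh)
    q[0] = qh[0]
    q[1] = qh[1]
    q[2] = qh[2]
    q[3] = qh[3]


@njit(cache=True, fastmath=True, error_model="numpy")
def sync_body_beads(pos, body_of, Xb, nb, bcom, bquat, Rbuf):
    for b in range(nb):
        _quat_to_rot(bquat[b], Rbuf[b])
    n = pos.shape[0]
    for i in range(n):
        b = body_of[i]
        if b >= 0:
            R = Rbuf[b]
            x, y, z = Xb[i, 0], Xb[i, 1], Xb[i, 2]
            pos[i, 0] = bcom[b, 0] + R[0, 0] * x + R[0, 1] * y + R[0, 2] * z
            pos[i, 1] = bcom[b, 1] + R[1, 0] * x + R[1, 1] * y + R[1, 2] * z
            pos[i, 2] = bcom[b, 2] + R[2, 0] * x + R[2, 1] * y + R[2, 2] * z


# --------------------------------------------------------------------------
# the integrator
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy")
def run_steps(nsteps, dt, kT,
              pos, vel, mass, gamma, cnoise, mobility, body_of,
              nb, bmass, binert, bcom, bquat, bvel, bang, Xb,
              bond_ij, bond_kind, bond_k, bond_r0, bond_rmax,
              ang_ijk, ang_kappa, ang_th0,
              dih_ijkl, dih_kappa, dih_phi0,
              bead_class, n_dna, peps_rep, peps_att, psig2, prc2, pshift,
              rlist2, excl_a, excl_b, nl_i, nl_j, n_pairs_arr,
              ref_pos, skin, fext, racc, rng_state):
    """Advance ``nsteps`` of velocity-Verlet Langevin dynamics.

    Returns 0 on success, -1 on neighbour-list overflow, 1 on a
    non-finite configuration.  ``racc`` accumulates the net conservative
    force on frozen beads (restraint-force bookkeeping).
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    bf = np.zeros((nb, 3))
    bt = np.zeros((nb, 3))
    Rbuf = np.zeros((nb, 3, 3))
    omega = np.zeros((nb, 3))
    half = 0.5 * dt
    n_pairs = n_pairs_arr[0]
    # displacement scan runs every few steps; the margin keeps the list
    # valid for the worst-case travel between scans
    scan_every = 8
    margin2 = (0.5 * skin - 0.12) ** 2
    since_scan = 0
    have_frozen = False
    for i in range(n):
        if mobility[i] == 0:
            have_frozen = True
            break

    bad = compute_forces(pos, f, bond_ij, bond_kind, bond_k, bond_r0,
                         bond_rmax, ang_ijk, ang_kappa, ang_th0,
                         dih_ijkl, dih_kappa, dih_phi0,
                         bead_class, n_dna, peps_rep, peps_att, psig2, prc2,
                         pshift, nl_i, nl_j, n_pairs, fext)
    _body_kinematics(nb, bquat, binert, bang, Rbuf, omega)
    # thermostat + aggregate at entry
    _apply_thermostat(pos, vel, f, gamma, cnoise, mobility, body_of, nb,
                      bcom, bvel, omega, rng_state)
    _aggregate_bodies(pos, f, body_of, nb, bcom, bf, bt)

    for _ in range(nsteps):
        # half kick
        for i in range(n):
            m = mobility[i]
            if m == 1:
                im = half / mass[i]
                vel[i, 0] += im * f[i, 0]
                vel[i, 1] += im * f[i, 1]
                vel[i, 2] += im * f[i, 2]
        for b in range(nb):
            im = half / bmass[b]
            bvel[b, 0] += im * bf[b, 0]
            bvel[b, 1] += im * bf[b, 1]
            bvel[b, 2] += im * bf[b, 2]
            bang[b, 0] += half * bt[b, 0]
            bang[b, 1] += half * bt[b, 1]
            bang[b, 2] += half * bt[b, 2]
        # drift
        for i in range(n):
            if mobility[i] == 1:
                pos[i, 0] += dt * vel[i, 0]
                pos[i, 1] += dt * vel[i, 1]
                pos[i, 2] += dt * vel[i, 2]
        for b in range(nb):
            bcom[b, 0] += dt * bvel[b, 0]
            bcom[b, 1] += dt * bvel[b, 1]
            bcom[b, 2] += dt * bvel[b, 2]
            _richardson_rotate(bquat[b], bang[b], binert[b], Rbuf[b], dt)
        sync_body_beads(pos, body_of, Xb, nb, bcom, bquat, Rbuf)

        # neighbour-list validity
        since_scan += 1
        if since_scan >= scan_every:
            since_scan = 0
            maxd2 = 0.0
            for i in range(n):
                dx = pos[i, 0] - ref_pos[i, 0]
                dy = pos[i, 1] - ref_pos[i, 1]
                dz = pos[i, 2] - ref_pos[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > maxd2:
                    maxd2 = d2
            if maxd2 > margin2:
                n_pairs = build_neighbor_list(pos, bead_class, n_dna, rlist2,
                                              excl_a, excl_b, nl_i, nl_j)
                if n_pairs < 0:
                    n_pairs_arr[0] = -1
                    return -1
                for i in range(n):
                    ref_pos[i, 0] = pos[i, 0]
                    ref_pos[i, 1] = pos[i, 1]
                    ref_pos[i, 2] = pos[i, 2]

        # forces at new positions
        bad += compute_forces(pos, f, bond_ij, bond_kind, bond_k, bond_r0,
                              bond_rmax, ang_ijk, ang_kappa, ang_th0,
                              dih_ijkl, dih_kappa, dih_phi0,
                              bead_class, n_dna, peps_rep, peps_att, psig2,
                              prc2, pshift, nl_i, nl_j, n_pairs, fext)
        # restraint bookkeeping for frozen beads (conservative force only)
        if have_frozen:
            for i in range(n):
                if mobility[i] == 0:
                    racc[i, 0] += f[i, 0]
                    racc[i, 1] += f[i, 1]
                    racc[i, 2] += f[i, 2]
        _body_kinematics(nb, bquat, binert, bang, Rbuf, omega)
        _apply_thermostat(pos, vel, f, gamma, cnoise, mobility, body_of, nb,
                          bcom, bvel, omega, rng_state)
        _aggregate_bodies(pos, f, body_of, nb, bcom, bf, bt)
        # second half kick
        for i in range(n):
            if mobility[i] == 1:
                im = half / mass[i]
                vel[i, 0] += im * f[i, 0]
                vel[i, 1] += im * f[i, 1]
                vel[i, 2] += im * f[i, 2]
        for b in range(nb):
            im = half / bmass[b]
            bvel[b, 0] += im * bf[b, 0]
            bvel[b, 1] += im * bf[b, 1]
            bvel[b, 2] += im * bf[b, 2]
            bang[b, 0] += half * bt[b, 0]
            bang[b, 1] += half * bt[b, 1]
            bang[b, 2] += half * bt[b, 2]

    n_pairs_arr[0] = n_pairs
    if bad > 0:
        for i in range(n):
            for c in range(3):
                if not np.isfinite(pos[i, c]):
                    return 1
    return 0


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _apply_thermostat(pos, vel, f, gamma, cnoise, mobility, body_of, nb, bcom,
                      bvel, omega, rng_state):
    """Add per-bead friction and random forces to ``f``."""
    n = pos.shape[0]
    for i in range(n):
        m = mobility[i]
        if m == 0:
            continue
        g = gamma[i]
        c = cnoise[i]
        if m == 1:
            vx, vy, vz = vel[i, 0], vel[i, 1], vel[i, 2]
        else:
            b = body_of[i]
            rx = pos[i, 0] - bcom[b, 0]
            ry = pos[i, 1] - bcom[b, 1]
            rz = pos[i, 2] - bcom[b, 2]
            ox, oy, oz = omega[b, 0], omega[b, 1], omega[b, 2]
            vx = bvel[b, 0] + oy * rz - oz * ry
            vy = bvel[b, 1] + oz * rx - ox * rz
            vz = bvel[b, 2] + ox * ry - oy * rx
        f[i, 0] += -g * vx + c * _rand_unitvar(rng_state)
        f[i, 1] += -g * vy + c * _rand_unitvar(rng_state)
        f[i, 2] += -g * vz + c * _rand_unitvar(rng_state)


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _aggregate_bodies(pos, f, body_of, nb, bcom, bf, bt):
    for b in range(nb):
        bf[b, 0] = 0.0
        bf[b, 1] = 0.0
        bf[b, 2] = 0.0
        bt[b, 0] = 0.0
        bt[b, 1] = 0.0
        bt[b, 2] = 0.0
    n = pos.shape[0]
    for i in range(n):
        b = body_of[i]
        if b < 0:
            continue
        fx, fy, fz = f[i, 0], f[i, 1], f[i, 2]
        bf[b, 0] += fx
        bf[b, 1] += fy
        bf[b, 2] += fz
        rx = pos[i, 0] - bcom[b, 0]
        ry = pos[i, 1] - bcom[b, 1]
        rz = pos[i, 2] - bcom[b, 2]
        bt[b, 0] += ry * fz - rz * fy
        bt[b, 1] += rz * fx - rx * fz
        bt[b, 2] += rx * fy - ry * fx


@njit(cache=True, fastmath=True, error_model="numpy")
def steepest_descent(niter, max_disp, ftol,
                     pos, mobility, body_of,
                     bond_ij, bond_kind, bond_k, bond_r0, bond_rmax,
                     ang_ijk, ang_kappa, ang_th0,
                     dih_ijkl, dih_kappa, dih_phi0,
                     bead_class, n_dna, peps_rep, peps_att, psig2, prc2,
                     pshift, rlist2, excl_a, excl_b, nl_i, nl_j, n_pairs_arr,
                     fext):
    """Clash-removing relaxation of the free beads (bodies held fixed)."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    for it in range(niter):
        if it % 25 == 0:
            np_ = build_neighbor_list(pos, bead_class, n_dna, rlist2,
                                      excl_a, excl_b, nl_i, nl_j)
            if np_ < 0:
                return -1
            n_pairs_arr[0] = np_
        compute_forces(pos, f, bond_ij, bond_kind, bond_k, bond_r0,
                       bond_rmax, ang_ijk, ang_kappa, ang_th0,
                       dih_ijkl, dih_kappa, dih_phi0,
                       bead_class, n_dna, peps_rep, peps_att, psig2, prc2,
                       pshift, nl_i, nl_j, n_pairs_arr[0], fext)
        fmax = 0.0
        for i in range(n):
            if mobility[i] != 1:
                continue
            fm = np.sqrt(f[i, 0] ** 2 + f[i, 1] ** 2 + f[i, 2] ** 2)
            if fm > fmax:
                fmax = fm
        if fmax < ftol:
            return it
        scale = max_disp / fmax if fmax > 0.0 else 0.0
        if scale > 0.002:
            scale = 0.002
        for i in range(n):
            if mobility[i] != 1:
                continue
            pos[i, 0] += scale * f[i, 0]
            pos[i, 1] += scale * f[i, 1]
            pos[i, 2] += scale * f[i, 2]
    return niter
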