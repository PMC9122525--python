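"""Independent equilibrium oracle for the discrete worm-like chain.

Computes the exact mean relative extension of a chain of unit tangents
with harmonic bending (energy ``kappa*gamma^2/2`` per joint) under a
stretching force, by numerical transfer-matrix integration over the
sphere (Gauss-Legendre nodes in cos(theta), azimuthal average of the
bending kernel).  This is the finite-force, finite-discretization
worm-like-chain law the simulated polymer should obey; it is evaluated
without any use of the dynamics code.
"""

import numpy as np
from numpy.polynomial.legendre import leggauss


def _log_partition(fb: float, kappa: float, n_bonds: int,
                   m: int = 48, nphi: int = 96) -> float:
    mu, w = leggauss(m)
    smu = np.sqrt(1.0 - mu ** 2)
    phi = np.linspace(0.0, 2.0 * np.pi, nphi, endpoint=False)
    cosg = (mu[:, None, None] * mu[None, :, None]
            + smu[:, None, None] * smu[None, :, None]
            * np.cos(phi)[None, None, :])
    np.clip(cosg, -1.0, 1.0, out=cosg)
    kernel = np.exp(-0.5 * kappa * np.arccos(cosg) ** 2).mean(axis=2)
    field = np.exp(fb * mu)
    T = kernel * (field * w)[None, :]
    vec = field * w
    logz = 0.0
    for _ in range(n_bonds - 1):
        vec = T @ vec
        s = vec.sum()
        logz += np.log(s)
        vec /= s
    return logz + np.log(vec.sum())


def discrete_wlc_extension(f_internal: float, kappa: float,
                           bond: float = 1.7, n_bonds: int = 300) -> float:
    """Mean relative extension <R_z>/(n_bonds*bond) at force f (kBT/nm)."""
    fb = f_internal * bond
    h = max(1e-4, 1e-3 * abs(fb))
    dlnz = (_log_partition(fb + h, kappa, n_bonds)
            - _log_partition(fb - h, kappa, n_bonds)) / (2.0 * h)
    return dlnz / n_bonds
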