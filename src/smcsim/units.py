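"""Unit system and physical constants.

All internal quantities use a reduced unit system chosen so that thermal
energies, nanometre geometry and the simulation clock are all O(1):

========  =========================================================
length    nanometre (nm)
energy    k_B*T at 300 K  (1 k_B*T = 4.14 pN*nm)
time      nLsec, i.e. 1e-9 of the simulation time unit "Lsec"
mass      derived: 1 internal mass = k_B*T * nLsec**2 / nm**2
          (equivalently 4.141 attogram, since
          1 ag*nm^2/nLsec^2 = 1e-21 J = 0.2415 k_B*T)
force     k_B*T / nm  (1 k_B*T/nm = 4.14 pN)
========  =========================================================

The simulation clock is *not* wall-clock seconds; trajectories are mapped
onto experimental seconds only through the analysis-level time calibration
(0.13 s per ATPase cycle).  Quantities in pN cross this boundary exactly
once, via :func:`pn_to_internal` / :func:`internal_to_pn`.
"""

from __future__ import annotations

from dataclasses import dataclass

#: k_B*T at 300 K expressed in pN*nm.
KT_PN_NM = 4.14

#: Conversion: 1 ag*nm^2/nLsec^2 in units of k_B*T (300 K).
#: 1 ag*nm^2/nLsec^2 = 1e-21 J; k_B*T(300 K) = 4.141e-21 J.
AG_TO_INTERNAL_MASS = 1.0 / 4.141

#: Simulation temperature (K); enters only through k_B*T = 1.
TEMPERATURE_K = 300.0

#: internal time unit expressed in Lsec
NLSEC_IN_LSEC = 1e-9


def pn_to_internal(force_pn: float) -> float:
    """Convert a force in pN to internal units (k_B*T / nm)."""
    return force_pn / KT_PN_NM


def internal_to_pn(force_internal: float) -> float:
    """Convert a force in internal units (k_B*T / nm) to pN."""
    return force_internal * KT_PN_NM


def ag_to_mass(mass_ag: float) -> float:
    """Convert a mass in attograms to internal mass units."""
    return mass_ag * AG_TO_INTERNAL_MASS


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of the unit conventions, echoed into run manifests."""

    length_unit: str = "nm"
    energy_unit: str = "kBT(300K)"
    time_unit: str = "nLsec"
    mass_unit: str = "kBT*nLsec^2/nm^2"
    kt_pn_nm: float = KT_PN_NM
    temperature_K: float = TEMPERATURE_K

    def as_dict(self) -> dict:
        return {
            "length_unit": self.length_unit,
            "energy_unit": self.energy_unit,
            "time_unit": self.time_unit,
            "mass_unit": self.mass_unit,
            "kT_pN_nm": self.kt_pn_nm,
            "temperature_K": self.temperature_K,
        }


UNITS = UnitSystem()
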