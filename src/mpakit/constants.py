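"""Physical constants and unit conversions used throughout the package.

All spectroscopy interfaces accept photon energies in eV; multiphoton
cross-section formulas are evaluated in Hartree atomic units internally.
The two frozen multiphoton conversion factors (``K_TPA_GM``, ``K_3PA``) are
the literature values of the prefactors that map the atomic-unit sums
``sum_i omega^2 delta_i g`` (TPA) and ``sum_i omega^3 delta_i g`` (3PA) onto
Goeppert-Mayer units and 1e-80 cm^6 s^2 / photon^2 respectively.  They are
reproducible from CODATA constants via :func:`derive_k_tpa` /
:func:`derive_k_3pa` to six significant figures (asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.constants as _sc

#: Hartree energy expressed in eV.
HARTREE_EV: float = _sc.value("Hartree energy in eV")

#: Bohr radius in cm.
BOHR_CM: float = _sc.value("Bohr radius") * 100.0

#: Atomic unit of time in s.
ATOMIC_TIME_S: float = _sc.value("atomic unit of time")

#: Speed of light in atomic units (inverse fine-structure constant).
C_AU: float = 1.0 / _sc.fine_structure

#: 1 GM = 1e-50 cm^4 s / photon.
GM_CM4S: float = 1e-50

#: TPA conversion factor: GM per (a.u. omega^2 * delta^TPA * g) — frozen
#: literature value.
K_TPA_GM: float = 2.505472e-2

#: 3PA conversion factor: 1e-80 cm^6 s^2 photon^-2 per
#: (a.u. omega^3 * delta^3PA * g) — frozen literature value.
K_3PA: float = 7.781292e-7


def derive_k_tpa() -> float:
    """Derive the TPA conversion factor from CODATA constants.

    The microscopic TPA cross section is ``8 pi^3 / c^2 * omega^2 delta g``
    in atomic units, where ``c`` is the speed of light in a.u.  The atomic
    unit of a TPA cross section is ``a0^4 * t0`` (cm^4 s); dividing by
    1e-50 cm^4 s expresses the result in GM.
    """
    return 8.0 * np.pi**3 / C_AU**2 * (BOHR_CM**4 * ATOMIC_TIME_S) / GM_CM4S


def derive_k_3pa() -> float:
    """Derive the 3PA conversion factor from CODATA constants.

    The microscopic 3PA cross section is ``16 pi^4 / c^3 * omega^3 delta g``
    in atomic units; its atomic unit is ``a0^6 * t0^2`` (cm^6 s^2), reported
    on a 1e-80 cm^6 s^2 scale.
    """
    return 16.0 * np.pi**4 / C_AU**3 * (BOHR_CM**6 * ATOMIC_TIME_S**2) / 1e-80


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (SI) plus the frozen multiphoton factors.

    Every field is strictly positive; validated on construction.
    """

    elementary_charge: float = _sc.e            # C
    electron_mass: float = _sc.m_e              # kg
    speed_of_light: float = _sc.c               # m/s
    vacuum_permittivity: float = _sc.epsilon_0  # F/m
    avogadro: float = _sc.N_A                   # 1/mol
    hbar: float = _sc.hbar                      # J s
    hartree_to_eV: float = HARTREE_EV
    bohr_to_cm: float = BOHR_CM
    atomic_time_to_s: float = ATOMIC_TIME_S
    k_tpa: float = K_TPA_GM
    k_3pa: float = K_3PA

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"constant {name!r} must be positive, got {value}")


CONSTANTS = PhysicalConstants()


def ev_to_hartree(energy_ev: np.ndarray | float) -> np.ndarray | float:
    """Convert energies in eV to Hartree."""
    return np.asarray(energy_ev) / HARTREE_EV if np.ndim(energy_ev) else energy_ev / HARTREE_EV
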