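"""Ensemble one-, two- and three-photon absorption spectra.

Per-snapshot excited-state data (excitation energy, oscillator strength,
two- and three-photon transition strengths) are broadened with unit-area
Lorentzians and averaged over the snapshot ensemble:

* OPA: molar absorption coefficient
  ``eps(w) = e^2 pi N_A / (2 ln10 eps0 n m_e c) * sum_i (w/w_i) f_i g(w, w_i, g_i)``
  evaluated in SI and reported in L mol^-1 cm^-1.
* TPA: ``sigma(w) = k_tpa * sum_i w^2 delta_i^TPA g(2w, w_i, g_i)`` in GM,
  with all quantities in atomic units inside the sum.
* 3PA: ``sigma(w) = k_3pa * sum_i w^3 delta_i^3PA g(3w, w_i, g_i)`` in
  1e-80 cm^6 s^2 / photon^2.

The ensemble spectrum is the arithmetic mean over snapshots, so intensities
are per-chromophore and independent of the number of snapshots.  The x-axis
is always the photon energy in eV: an isolated TPA (3PA) band therefore
peaks near half (a third of) the transition energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CONSTANTS, HARTREE_EV, K_3PA, K_TPA_GM

__all__ = [
    "ExcitedStateRecord",
    "SnapshotRecord",
    "BroadeningSpec",
    "Spectrum",
    "PeakTable",
    "lorentzian",
    "opa_epsilon",
    "tpa_sigma",
    "threepa_sigma",
    "find_peaks",
    "peak_deviation",
    "default_grid",
    "default_band_windows",
]

#: Default photon-energy grid: 0–6 eV in 0.002 eV steps.
DEFAULT_GRID_MAX_EV = 6.0
DEFAULT_GRID_STEP_EV = 0.002
#: Default Lorentzian half-width at half-maximum, eV.
DEFAULT_GAMMA_EV = 0.1

OPA_UNITS = "L mol^-1 cm^-1"
TPA_UNITS = "GM"
THREEPA_UNITS = "1e-80 cm^6 s^2 photon^-2"


@dataclass(frozen=True)
class ExcitedStateRecord:
    """One electronic state of one snapshot."""

    state_index: int
    energy: float                 # eV
    oscillator_strength: float = 0.0
    delta_tpa: float = 0.0        # a.u.
    delta_3pa: float = 0.0        # a.u.

    def __post_init__(self) -> None:
        if self.state_index < 1:
            raise ValueError("state_index must be >= 1")
        if not self.energy > 0:
            raise ValueError("excitation energy must be positive")
        for name in ("oscillator_strength", "delta_tpa", "delta_3pa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SnapshotRecord:
    """All computed excited states of one trajectory snapshot."""

    snapshot_id: int
    time: float                   # fs
    chromophore: str
    states: tuple[ExcitedStateRecord, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("a snapshot needs at least one state")
        idx = [s.state_index for s in self.states]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("state indices must be strictly increasing")

    def state(self, index: int) -> ExcitedStateRecord:
        for s in self.states:
            if s.state_index == index:
                return s
        raise KeyError(f"state {index} not present in snapshot {self.snapshot_id}")


@dataclass(frozen=True)
class BroadeningSpec:
    """Lorentzian broadening; ``gamma`` is the HWHM in eV.

    ``gamma`` may be a scalar (applied to every state) or a mapping from
    state index to HWHM.
    """

    gamma: float | Mapping[int, float] = DEFAULT_GAMMA_EV
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.lineshape != "lorentzian":
            raise ValueError(f"unsupported lineshape {self.lineshape!r}")
        gammas = self.gamma.values() if isinstance(self.gamma, Mapping) else [self.gamma]
        if any(not g > 0 for g in gammas):
            raise ValueError("gamma (HWHM) must be positive")

    def gamma_for(self, state_index: int) -> float:
        if isinstance(self.gamma, Mapping):
            return float(self.gamma[state_index])
        return float(self.gamma)


@dataclass
class Spectrum:
    """Intensity on a photon-energy grid with process and unit tags."""

    grid: np.ndarray              # eV, strictly increasing
    intensity: np.ndarray
    process: str                  # OPA | TPA | 3PA
    units: str
    refractive_index: float = 1.0
    gamma: float | Mapping[int, float] = DEFAULT_GAMMA_EV
    n_snapshots: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape:
            raise ValueError("grid and intensity shapes differ")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.intensity < -1e-300):
            raise ValueError("negative intensity")


@dataclass
class PeakTable:
    """One row per requested band: peak position on the grid and its height."""

    band_index: np.ndarray
    peak_energy: np.ndarray       # eV
    peak_intensity: np.ndarray    # spectrum units
    units: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_index": np.asarray(self.band_index, dtype=int),
                "peak_energy_eV": self.peak_energy,
                "peak_intensity": self.peak_intensity,
            }
        )


def lorentzian(x, x0, gamma):
    """Unit-area Lorentzian ``(1/pi) * gamma / ((x - x0)^2 + gamma^2)``.

    ``x``, ``x0`` and the HWHM ``gamma`` must share one unit; the returned
    density carries the inverse of that unit.
    """
    if not gamma > 0:
        raise ValueError("gamma (HWHM) must be positive")
    x = np.asarray(x, dtype=float)
    return (gamma / math.pi) / ((x - x0) ** 2 + gamma**2)


def default_grid(
    max_ev: float = DEFAULT_GRID_MAX_EV, step_ev: float = DEFAULT_GRID_STEP_EV
) -> np.ndarray:
    """Photon-energy grid from ``step`` to ``max`` inclusive (eV)."""
    n = int(round(max_ev / step_ev))
    return np.arange(1, n + 1) * step_ev


def _check_inputs(records: Sequence[SnapshotRecord], grid: np.ndarray) -> np.ndarray:
    if len(records) == 0:
        raise ValueError("empty snapshot record list")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    return grid


def opa_epsilon(
    records: Sequence[SnapshotRecord],
    grid: np.ndarray | None = None,
    broadening: BroadeningSpec | None = None,
    refractive_index: float = 1.0,
) -> Spectrum:
    """Ensemble-mean molar absorption coefficient, L mol^-1 cm^-1.

    Each state contributes ``P * (w / w_i) * f_i * g(w, w_i, gamma_i)`` with
    the SI prefactor ``P = e^2 pi N_A hbar / (2 ln10 eps0 n m_e c)``; the
    Lorentzian is evaluated per Joule (hence the extra hbar relative to a
    per-angular-frequency density).  The SI result (m^2/mol) is converted to
    L mol^-1 cm^-1 by the factor 10 (1 m^2/mol = 1e4 cm^2/mol = 10 L mol^-1 cm^-1).
    """
    broadening = broadening or BroadeningSpec()
    grid = _check_inputs(records, default_grid() if grid is None else grid)
    c = CONSTANTS
    prefactor_si = (c.elementary_charge**2 * math.pi * c.avogadro * c.hbar) / (
        2.0
        * math.log(10.0)
        * c.vacuum_permittivity
        * refractive_index
        * c.electron_mass
        * c.speed_of_light
    )
    ev_to_joule = c.elementary_charge
    total = np.zeros_like(grid)
    for snap in records:
        for st in snap.states:
            g_ev = lorentzian(grid, st.energy, broadening.gamma_for(st.state_index))
            total += (
                prefactor_si
                * (grid / st.energy)
                * st.oscillator_strength
                * (g_ev / ev_to_joule)
            )
    intensity = total / len(records) * 10.0  # m^2/mol -> L mol^-1 cm^-1
    return Spectrum(
        grid=grid,
        intensity=intensity,
        process="OPA",
        units=OPA_UNITS,
        refractive_index=refractive_index,
        gamma=broadening.gamma,
        n_snapshots=len(records),
    )


def _multiphoton(
    records: Sequence[SnapshotRecord],
    grid: np.ndarray,
    broadening: BroadeningSpec,
    n_photons: int,
) -> np.ndarray:
    """Atomic-unit multiphoton sum; grid is photon energy in eV."""
    w_au = grid / HARTREE_EV
    total = np.zeros_like(grid)
    attr = {2: "delta_tpa", 3: "delta_3pa"}[n_photons]
    k = {2: K_TPA_GM, 3: K_3PA}[n_photons]
    for snap in records:
        for st in snap.states:
            delta = getattr(st, attr)
            if delta == 0.0:
                continue
            gamma_au = broadening.gamma_for(st.state_index) / HARTREE_EV
            g_au = lorentzian(n_photons * w_au, st.energy / HARTREE_EV, gamma_au)
            total += k * w_au**n_photons * delta * g_au
    return total / len(records)


def tpa_sigma(
    records: Sequence[SnapshotRecord],
    grid: np.ndarray | None = None,
    broadening: BroadeningSpec | None = None,
) -> Spectrum:
    """Ensemble-mean two-photon absorption cross section in GM.

    The sum ``k_tpa * w^2 * delta_i^TPA * g(2w, w_i, gamma_i)`` is evaluated
    with photon energy, transition energy and HWHM in atomic units; an
    isolated band peaks near ``w_i / 2`` on the photon-energy axis.
    """
    broadening = broadening or BroadeningSpec()
    grid = _check_inputs(records, default_grid() if grid is None else grid)
    intensity = _multiphoton(records, grid, broadening, 2)
    return Spectrum(
        grid=grid,
        intensity=intensity,
        process="TPA",
        units=TPA_UNITS,
        gamma=broadening.gamma,
        n_snapshots=len(records),
    )


def threepa_sigma(
    records: Sequence[SnapshotRecord],
    grid: np.ndarray | None = None,
    broadening: BroadeningSpec | None = None,
) -> Spectrum:
    """Ensemble-mean three-photon absorption cross section.

    Reported in 1e-80 cm^6 s^2 / photon^2; an isolated band peaks near
    ``w_i / 3`` on the photon-energy axis.
    """
    broadening = broadening or BroadeningSpec()
    grid = _check_inputs(records, default_grid() if grid is None else grid)
    intensity = _multiphoton(records, grid, broadening, 3)
    return Spectrum(
        grid=grid,
        intensity=intensity,
        process="3PA",
        units=THREEPA_UNITS,
        gamma=broadening.gamma,
        n_snapshots=len(records),
    )


def default_band_windows(
    records: Sequence[SnapshotRecord],
    broadening: BroadeningSpec | None = None,
    states: Sequence[int] | None = None,
    photon_order: int = 1,
) -> list[tuple[float, float]]:
    """Band windows of +-3 gamma around each ensemble-mean state energy.

    For multiphoton spectra pass ``photon_order`` 2 or 3 so the windows sit
    at ``E_i / order`` on the photon-energy axis.
    """
    broadening = broadening or BroadeningSpec()
    if states is None:
        states = sorted({s.state_index for r in records for s in r.states})
    windows = []
    for i in states:
        energies = [r.state(i).energy for r in records]
        center = float(np.mean(energies)) / photon_order
        half = 3.0 * broadening.gamma_for(i) / photon_order
        windows.append((center - half, center + half))
    return windows


def find_peaks(spectrum: Spectrum, bands: Sequence[tuple[float, float]]) -> PeakTable:
    """Locate the maximum-intensity grid point inside each energy window.

    Ties break toward lower energy.  A window with no intensity above zero
    raises, as does a window that contains no grid point.
    """
    peak_e, peak_i = [], []
    for lo, hi in bands:
        mask = (spectrum.grid >= lo) & (spectrum.grid <= hi)
        if not mask.any():
            raise ValueError(f"empty band window ({lo}, {hi}): no grid points")
        seg = spectrum.intensity[mask]
        if np.max(seg) <= 0:
            raise ValueError(f"no peak above zero in window ({lo}, {hi})")
        j = int(np.argmax(seg))  # first == lowest-energy on an increasing grid
        peak_e.append(spectrum.grid[mask][j])
        peak_i.append(seg[j])
    return PeakTable(
        band_index=np.arange(1, len(bands) + 1),
        peak_energy=np.asarray(peak_e),
        peak_intensity=np.asarray(peak_i),
        units=spectrum.units,
    )


def peak_deviation(peaks_a: PeakTable, peaks_b: PeakTable) -> pd.DataFrame:
    """Band-by-band |E_a - E_b| (eV) and signed intensity difference.

    Used both for theory-vs-experiment and ensemble-vs-ensemble comparisons;
    both tables must list the same bands in matching units.
    """
    if len(peaks_a.band_index) != len(peaks_b.band_index) or np.any(
        np.asarray(peaks_a.band_index) != np.asarray(peaks_b.band_index)
    ):
        raise ValueError("band mismatch between peak tables")
    if peaks_a.units and peaks_b.units and peaks_a.units != peaks_b.units:
        raise ValueError("peak tables carry different intensity units")
    return pd.DataFrame(
        {
            "band_index": np.asarray(peaks_a.band_index, dtype=int),
            "abs_delta_energy_eV": np.abs(peaks_a.peak_energy - peaks_b.peak_energy),
            "delta_intensity": peaks_a.peak_intensity - peaks_b.peak_intensity,
        }
    )
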