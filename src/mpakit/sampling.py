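"""Snapshot decorrelation analysis: how far apart must snapshots be sampled?

The autocorrelation of a per-snapshot observable (typically the TPA cross
section of the lowest transition) is computed with the biased population
normalization

    C(k) = 1/(n sigma^2) * sum_{t=1}^{n-k} (x_t - mu)(x_{t+k} - mu),

fitted to ``A exp(-t/tau)``, and the fitted decay converted into a
recommended sampling interval: the smallest frame multiple at which the
fitted correlation falls below a tolerance.  A down-sampling convergence
study recomputes ensemble spectra at coarser spacings and reports peak
drift and distribution summaries.

Note on bias: with the 1/n prefactor and the truncated sum, C(0) = 1
exactly, but C(k) for k > 0 underestimates the true autocorrelation by a
factor approaching (n-k)/n.  This matches the printed definition and is
negligible for k << n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .spectra import (
    BroadeningSpec,
    PeakTable,
    SnapshotRecord,
    default_band_windows,
    find_peaks,
    tpa_sigma,
)
from .constants import HARTREE_EV, K_TPA_GM

__all__ = [
    "TimeSeries",
    "AcfResult",
    "autocorr",
    "fit_exponential",
    "decorrelation_spacing",
    "downsample_convergence",
    "tpa_peak_series",
]

DEFAULT_TOLERANCE = 0.01


@dataclass
class TimeSeries:
    """Uniformly spaced observable timeline (times in fs)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values differ in length")
        if self.times.size < 3:
            raise ValueError("need at least 3 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dt) > 1e-6 * dt[0]:
            raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class AcfResult:
    """Lagged autocorrelation plus (optionally) the exponential fit."""

    lags: np.ndarray              # fs
    c: np.ndarray                 # dimensionless
    amplitude: float | None = None   # A
    tau: float | None = None         # fs
    spacing: float | None = None     # recommended sampling interval, fs
    tolerance: float | None = None


def autocorr(series: TimeSeries, max_lag: int) -> AcfResult:
    """Biased-normalization autocorrelation out to ``max_lag`` frames.

    Uses the population mean and variance of the full series; C(0) = 1 by
    construction.  A constant series (zero variance) is rejected.
    """
    x = series.values
    n = x.size
    if not 0 < max_lag < n:
        raise ValueError("max_lag must satisfy 0 < max_lag < n")
    mu = x.mean()
    var = np.mean((x - mu) ** 2)
    if var == 0:
        raise ValueError("zero variance: autocorrelation undefined for a constant series")
    d = x - mu
    c = np.array([np.dot(d[: n - k], d[k:]) / (n * var) for k in range(max_lag + 1)])
    lags = np.arange(max_lag + 1) * series.dt
    return AcfResult(lags=lags, c=c)


def fit_exponential(
    acf: AcfResult, fit_window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Nonlinear least-squares fit of ``A exp(-t/tau)`` to C(t).

    Initialization: A from C at the first lag, tau from the first lag where
    C drops below C(0)/e.  The fitted (A, tau) are stored on ``acf`` and
    returned.  Raises if the window holds fewer than 4 lags or if no decay
    is detectable (C never drops below C(0)/e and is non-decreasing).
    """
    if fit_window is None:
        lo, hi = 0.0, float(acf.lags[-1])
    else:
        lo, hi = fit_window
    mask = (acf.lags >= lo) & (acf.lags <= hi)
    t, c = acf.lags[mask], acf.c[mask]
    if t.size < 4:
        raise ValueError("need at least 4 lags in the fit window")
    c0 = acf.c[0]
    below = np.nonzero(acf.c < c0 / np.e)[0]
    if below.size == 0 and np.all(np.diff(acf.c) >= 0):
        raise ValueError("no decay detected in autocorrelation")
    tau0 = acf.lags[below[0]] if below.size else acf.lags[-1]
    tau0 = max(float(tau0), float(acf.lags[1]) if acf.lags.size > 1 else 1.0)
    a0 = float(acf.c[1]) if acf.c.size > 1 else float(c0)
    a0 = a0 if a0 > 0 else float(c0)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t,
            c,
            p0=(a0, tau0),
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise ValueError(f"exponential fit did not converge: {err}") from err
    amplitude, tau = float(popt[0]), float(popt[1])
    dt = float(acf.lags[1] - acf.lags[0]) if acf.lags.size > 1 else 0.0
    if dt and tau < dt:
        raise ValueError(
            f"fitted tau = {tau:.3g} fs is below one frame spacing ({dt:.3g} fs): "
            "no resolvable decay"
        )
    acf.amplitude, acf.tau = amplitude, tau
    return amplitude, tau


def decorrelation_spacing(
    amplitude: float,
    tau: float,
    tolerance: float = DEFAULT_TOLERANCE,
    frame_interval: float = 5.0,
) -> float:
    """Smallest multiple of ``frame_interval`` with ``A exp(-t/tau) < tol``.

    Closed form ``t* = tau ln(A / tol)`` rounded up to the frame grid; a
    tolerance at or above A needs no waiting and is rejected as ill-posed.
    """
    if tolerance >= amplitude:
        raise ValueError("tolerance must be below the fitted amplitude A")
    if tau <= 0:
        return frame_interval
    t_star = tau * np.log(amplitude / tolerance)
    n = max(1, int(np.ceil(t_star / frame_interval - 1e-12)))
    return n * frame_interval


def tpa_peak_series(
    records: Sequence[SnapshotRecord],
    state_index: int = 1,
    broadening: BroadeningSpec | None = None,
) -> TimeSeries:
    """Per-snapshot peak TPA cross section of one state, as a time series.

    For an isolated Lorentzian band the photon-energy peak height is
    ``k_tpa (w_i/2)^2 delta_i / (pi gamma_au)`` in GM — evaluated directly
    rather than via a grid.
    """
    broadening = broadening or BroadeningSpec()
    times, values = [], []
    for r in records:
        st = r.state(state_index)
        w_au = st.energy / HARTREE_EV
        gamma_au = broadening.gamma_for(state_index) / HARTREE_EV
        times.append(r.time)
        values.append(K_TPA_GM * (w_au / 2.0) ** 2 * st.delta_tpa / (np.pi * gamma_au))
    return TimeSeries(times=np.array(times), values=np.array(values))


def _moment_summary(x: np.ndarray) -> dict[str, float]:
    # ptp, not sd: the pairwise-summed mean of a constant array can be off
    # by an ulp, making np.std spuriously nonzero
    degenerate = np.ptp(x) == 0.0
    sd = float(np.std(x, ddof=1)) if x.size > 1 and not degenerate else 0.0
    return {
        "mean": float(np.mean(x)),
        "sd": sd,
        "skewness": float(stats.skew(x, bias=False)) if x.size > 2 and not degenerate else 0.0,
        "excess_kurtosis": (
            float(stats.kurtosis(x, bias=False)) if x.size > 3 and not degenerate else 0.0
        ),
    }


def downsample_convergence(
    records: Sequence[SnapshotRecord],
    spacings: Sequence[float],
    grid: np.ndarray | None = None,
    broadening: BroadeningSpec | None = None,
    state_index: int = 1,
) -> dict[float, dict]:
    """Recompute ensemble TPA spectra at coarser snapshot spacings.

    ``spacings`` are in fs and must be integer multiples of the record
    interval.  For each spacing the result holds the peak table, the peak
    drift (eV) relative to the densest spacing, the retained snapshot count
    and moment summaries (mean, sd, skewness, excess kurtosis) of the first
    excitation energy, oscillator strength and per-snapshot TPA peak height.
    """
    broadening = broadening or BroadeningSpec()
    records = sorted(records, key=lambda r: r.time)
    times = np.array([r.time for r in records])
    if times.size < 2:
        raise ValueError("need at least 2 snapshots")
    dt = float(np.min(np.diff(times)))
    results: dict[float, dict] = {}
    ref_peaks: PeakTable | None = None
    for spacing in sorted(spacings):
        ratio = spacing / dt
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError(
                f"spacing {spacing} fs is not a multiple of the record interval {dt} fs"
            )
        step = int(round(ratio))
        subset = records[::step]
        if len(subset) < 2:
            raise ValueError(f"insufficient snapshots after downsampling to {spacing} fs")
        spec = tpa_sigma(subset, grid, broadening)
        windows = default_band_windows(subset, broadening, photon_order=2)
        peaks = find_peaks(spec, windows)
        if ref_peaks is None:
            ref_peaks = peaks
        drift = np.abs(peaks.peak_energy - ref_peaks.peak_energy)
        e1 = np.array([r.state(state_index).energy for r in subset])
        fosc = np.array([r.state(state_index).oscillator_strength for r in subset])
        sigma = tpa_peak_series(subset, state_index, broadening).values
        results[spacing] = {
            "n_snapshots": len(subset),
            "peaks": peaks,
            "peak_drift_eV": drift,
            "summaries": {
                "energy_eV": _moment_summary(e1),
                "oscillator_strength": _moment_summary(fosc),
                "sigma_tpa_GM": _moment_summary(sigma),
            },
        }
    return results
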