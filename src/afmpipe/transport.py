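"""Transport coefficients: diffusion from mean-squared displacement and
shear viscosity from the Green-Kubo stress autocorrelation integral.

The diffusion constant uses the Einstein relation D = slope/6 of the MSD in
its diffusive (linear) regime, with multiple time origins for variance
reduction.  Viscosity integrates the autocorrelation of the off-diagonal
pressure components,

    eta = V/(k_B T) * integral <P_ab(0) P_ab(t)> dt,

averaged over the xy, xz and yz components, with the integral truncated at
the first zero crossing of the averaged autocorrelation (capped at max lag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import A2_PER_PS_TO_CM2_PER_S, KB_J_PER_K


class DiffusiveRegimeError(ValueError):
    """The MSD fit window is not in the diffusive (linear) regime."""


@dataclass
class MSDCurve:
    lag: np.ndarray          # ps
    msd: np.ndarray          # A^2, averaged over particles and origins
    per_particle: np.ndarray | None = None  # (n_lags, n_particles)
    n_origins: int = 1

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if self.lag.shape != self.msd.shape:
            raise ValueError("lag and MSD must align")
        if self.lag[0] != 0 or self.msd[0] != 0:
            raise ValueError("MSD must start at (0, 0)")
        if np.any(self.msd < 0):
            raise ValueError("negative MSD")


@dataclass
class StressSeries:
    time: np.ndarray     # ps
    p_xy: np.ndarray     # bar
    p_xz: np.ndarray
    p_yz: np.ndarray
    volume: float        # nm^3
    T: float             # K

    def __post_init__(self) -> None:
        n = len(self.time)
        for c in (self.p_xy, self.p_xz, self.p_yz):
            if len(c) != n:
                raise ValueError("stress columns must have equal length")


# ---------------------------------------------------------------------------
# Mean-squared displacement
# ---------------------------------------------------------------------------

def msd_from_trajectory(positions: np.ndarray, dt: float,
                        origin_stride: int = 10,
                        n_lags: int = 100,
                        max_lag_fraction: float = 0.5) -> MSDCurve:
    """MSD over multiple time origins.

    ``positions``: (n_frames, n_particles, 3) unwrapped coordinates in
    Angstrom; ``dt`` frame spacing in ps.  Lags are evaluated on an evenly
    spaced subsample up to ``max_lag_fraction`` of the trajectory.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    n_frames, n_part, _ = pos.shape
    max_lag = int(max_lag_fraction * (n_frames - 1))
    if max_lag < 1:
        raise ValueError("trajectory too short")
    lags = np.unique(np.linspace(0, max_lag, min(n_lags, max_lag) + 1).astype(int))
    per_particle = np.zeros((len(lags), n_part))
    n_origins = 0
    for li, lag in enumerate(lags):
        if lag == 0:
            continue
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = pos[origins + lag] - pos[origins]
        per_particle[li] = np.mean(np.sum(disp**2, axis=-1), axis=0)
        n_origins = max(n_origins, len(origins))
    return MSDCurve(lag=lags * dt, msd=per_particle.mean(axis=1),
                    per_particle=per_particle, n_origins=n_origins)


def diffusion_from_msd(curve: MSDCurve,
                       window: tuple[float, float] = (0.2, 0.8),
                       regime_tolerance: float = 0.4
                       ) -> tuple[float, float]:
    """Einstein-relation diffusion constant (cm^2/s) and SE.

    Fits MSD = 6 D t over the window (fractions of the maximum lag).  The
    log-log slope over the window must be 1 within ``regime_tolerance`` —
    ballistic motion (slope 2) or caging reject the fit.  A negative fitted
    slope yields NaN with a warning.  The SE pools per-particle estimates
    when available.
    """
    tmax = curve.lag[-1]
    sel = (curve.lag >= window[0] * tmax) & (curve.lag <= window[1] * tmax)
    if sel.sum() < 2:
        raise ValueError("too few lags in the fit window")
    t = curve.lag[sel]
    y = curve.msd[sel]
    if np.all(y > 0):
        loglog_slope = np.polyfit(np.log(t), np.log(y), 1)[0]
        if abs(loglog_slope - 1.0) > regime_tolerance:
            raise DiffusiveRegimeError(
                f"log-log MSD slope {loglog_slope:.2f} is not diffusive"
            )
    slope = np.polyfit(t, y, 1)[0]
    if slope < 0:
        warnings.warn("negative MSD slope; returning NaN", RuntimeWarning)
        return float("nan"), float("nan")
    D = slope / 6.0 * A2_PER_PS_TO_CM2_PER_S
    se = 0.0
    if curve.per_particle is not None and curve.per_particle.shape[1] > 1:
        slopes = np.polyfit(t, curve.per_particle[sel], 1)[0]
        d_i = slopes / 6.0 * A2_PER_PS_TO_CM2_PER_S
        se = float(np.std(d_i, ddof=1) / np.sqrt(len(d_i)))
    return float(D), se


# ---------------------------------------------------------------------------
# Green-Kubo viscosity
# ---------------------------------------------------------------------------

def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Stationary autocorrelation <x(0) x(t)> for lags 0..max_lag (FFT)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max lag must be shorter than the series")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return acf / counts


def viscosity_from_acf(acf: np.ndarray, dt: float, volume: float, T: float,
                       cutoff: str | int = "zero-crossing"
                       ) -> float:
    """eta (mPa*s) from a stress ACF (bar^2), trapezoidal integration.

    ``cutoff``: "zero-crossing" truncates at the first sign change of the
    ACF; an integer truncates at that lag index.
    """
    acf = np.asarray(acf, dtype=float)
    if cutoff == "zero-crossing":
        neg = np.nonzero(acf <= 0)[0]
        end = int(neg[0]) if len(neg) else len(acf) - 1
        end = max(end, 1)
    else:
        end = min(int(cutoff), len(acf) - 1)
    integral = np.trapezoid(acf[: end + 1], dx=dt)  # bar^2 * ps
    # bar^2 ps -> Pa^2 s: 1e10 * 1e-12; volume nm^3 -> m^3: 1e-27
    eta_pa_s = volume * 1e-27 / (KB_J_PER_K * T) * integral * 1e10 * 1e-12
    return float(eta_pa_s * 1e3)


def viscosity_green_kubo(series: StressSeries, max_lag: int,
                         cutoff: str | int = "zero-crossing"
                         ) -> tuple[float, float]:
    """Green-Kubo shear viscosity (mPa*s) with an SE over the three
    off-diagonal components."""
    n = len(series.time)
    if max_lag >= n:
        raise ValueError("max lag must be shorter than the series")
    dt = float(series.time[1] - series.time[0]) if n > 1 else 1.0
    comps = [series.p_xy, series.p_xz, series.p_yz]
    acfs = [autocorrelation(np.asarray(c, float) - np.mean(c), max_lag)
            for c in comps]
    mean_acf = np.mean(acfs, axis=0)
    # shared cutoff from the averaged ACF, applied to every component
    if cutoff == "zero-crossing":
        neg = np.nonzero(mean_acf <= 0)[0]
        end = int(neg[0]) if len(neg) else max_lag
        end = max(end, 1)
    else:
        end = min(int(cutoff), max_lag)
    etas = [viscosity_from_acf(a, dt, series.volume, series.T, cutoff=end)
            for a in acfs]
    eta = float(np.mean(etas))
    se = float(np.std(etas, ddof=1) / np.sqrt(len(etas))) if len(etas) > 1 else 0.0
    return eta, se
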