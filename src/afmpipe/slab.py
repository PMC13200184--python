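"""Slab-geometry observables: density profiles, cavity-robust liquid
density, coexistence densities and pressure-tensor surface tension.

A liquid-vapor (or liquid-liquid) slab spans the box along one axis; the
surface tension follows from the time-averaged pressure anisotropy

    gamma = (L_Z / 2) * (<P_Z> - (<P_X> + <P_Y>) / 2)

where the factor L_Z/2 accounts for the two interfaces of the slab.  Liquid
densities are measured with a two-step procedure: first locate the liquid
region (longest contiguous run of bins above a threshold), then average only
over its central core.  This makes the estimate robust against the large
interfacial cavities that low-surface-tension liquids develop, which bias any
naive "densest region" shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AMU_PER_A3_TO_G_PER_L, BAR_NM_TO_MN_PER_M
from .model_core import Configuration


class NoLiquidRegionError(ValueError):
    """No bin exceeds the liquid threshold."""


class NoVaporRegionError(ValueError):
    """Vapor region shorter than the buffer."""


@dataclass
class DensityProfile:
    """Mass density binned along the slab normal."""

    bin_centers: np.ndarray   # nm
    density: np.ndarray       # g/L
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_centers.shape != self.density.shape:
            raise ValueError("bin centers and densities must align")
        widths = np.diff(self.bin_centers)
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")
        if np.any(self.density < 0):
            raise ValueError("negative density")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass
class PressureTensorSeries:
    """Time-resolved diagonal pressure components of a slab simulation."""

    time: np.ndarray   # ps
    p_x: np.ndarray    # bar
    p_y: np.ndarray
    p_z: np.ndarray
    box_lz: float      # nm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.p_x = np.asarray(self.p_x, dtype=float)
        self.p_y = np.asarray(self.p_y, dtype=float)
        self.p_z = np.asarray(self.p_z, dtype=float)
        n = len(self.time)
        if not (len(self.p_x) == len(self.p_y) == len(self.p_z) == n):
            raise ValueError("pressure columns must have equal length")
        if self.box_lz <= 0:
            raise ValueError("box length L_Z must be positive")


# ---------------------------------------------------------------------------
# Density profiles
# ---------------------------------------------------------------------------

def density_profile(frames: list[Configuration], axis: int = 2,
                    n_bins: int = 100) -> DensityProfile:
    """Mass-weighted density profile averaged over frames (output g/L, nm).

    Coordinates are wrapped into the box along the chosen axis; the box must
    be consistent across frames.
    """
    if not frames:
        raise ValueError("zero frames")
    if n_bins < 10:
        raise ValueError("need at least 10 bins")
    box = frames[0].box
    if box is None:
        raise ValueError("density profile requires a box")
    for f in frames:
        if f.box is None or not np.allclose(f.box, box):
            raise ValueError("inconsistent box across frames")
    L = float(box[axis])
    other = [i for i in range(3) if i != axis]
    area = float(box[other[0]] * box[other[1]])
    bin_w = L / n_bins
    hist = np.zeros(n_bins)
    for f in frames:
        z = np.mod(f.coords[:, axis], L)
        idx = np.minimum((z / bin_w).astype(int), n_bins - 1)
        np.add.at(hist, idx, f.masses())
    hist /= len(frames)
    vol = area * bin_w  # A^3
    dens = hist / vol * AMU_PER_A3_TO_G_PER_L
    centers = (np.arange(n_bins) + 0.5) * bin_w / 10.0  # A -> nm
    return DensityProfile(bin_centers=centers, density=dens, n_frames=len(frames))


def _liquid_run(profile: DensityProfile, interface_threshold: float
                ) -> tuple[np.ndarray, float]:
    """Longest contiguous run of bins above the threshold.

    The profile is treated as periodic along the slab normal: it is rolled so
    the least-dense bin sits at the edge, which unwraps any run crossing the
    boundary.  Returns (indices into the rolled profile, roll offset).
    """
    d = profile.density
    lo, hi = float(np.min(d)), float(np.max(d))
    if hi - lo <= 1e-12 * max(hi, 1.0):
        raise NoLiquidRegionError(
            "profile has no density contrast; no liquid region identifiable"
        )
    thr = lo + interface_threshold * (hi - lo)
    shift = -int(np.argmin(d))
    rolled = np.roll(d, shift)
    above = rolled >= thr
    if not above.any():
        raise NoLiquidRegionError("no bin exceeds the liquid threshold")
    # longest run of True
    best_start = best_len = cur_start = cur_len = 0
    for i, a in enumerate(above):
        if a:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    return np.arange(best_start, best_start + best_len), shift


def liquid_core_density(profile: DensityProfile,
                        interface_threshold: float = 0.5,
                        core_fraction: float = 0.5) -> float:
    """Two-step liquid density: mean over the central ``core_fraction`` of
    the longest above-threshold run (g/L)."""
    if not 0 < core_fraction <= 1:
        raise ValueError("core fraction must be in (0, 1]")
    run, shift = _liquid_run(profile, interface_threshold)
    n_core = max(1, int(round(core_fraction * len(run))))
    start = (len(run) - n_core) // 2
    core = run[start:start + n_core]
    rolled = np.roll(profile.density, shift)
    return float(np.mean(rolled[core]))


def coexistence_densities(profile: DensityProfile,
                          interface_threshold: float = 0.5,
                          core_fraction: float = 0.5,
                          vapor_buffer: float = 1.0) -> tuple[float, float]:
    """(rho_l, rho_g) in g/L; the vapor mean excludes a buffer (nm) around
    the liquid run."""
    rho_l = liquid_core_density(profile, interface_threshold, core_fraction)
    run, shift = _liquid_run(profile, interface_threshold)
    n = len(profile.density)
    buf_bins = int(np.ceil(vapor_buffer / profile.bin_width))
    vapor_mask = np.ones(n, dtype=bool)
    lo = run[0] - buf_bins
    hi = run[-1] + buf_bins
    vapor_mask[max(lo, 0):min(hi + 1, n)] = False
    if lo < 0:
        vapor_mask[lo % n:] = False
    if hi >= n:
        vapor_mask[:hi % n + 1] = False
    if not vapor_mask.any():
        raise NoVaporRegionError("vapor region shorter than the buffer")
    rolled = np.roll(profile.density, shift)
    rho_g = float(np.mean(rolled[vapor_mask]))
    return rho_l, rho_g


# ---------------------------------------------------------------------------
# Pressure-tensor estimators
# ---------------------------------------------------------------------------

def _block_mean_se(x: np.ndarray, n_blocks: int) -> tuple[float, float]:
    """Mean and block-averaged standard error (1 sigma)."""
    x = np.asarray(x, dtype=float)
    mean = float(np.mean(x))
    if len(x) < 2 * n_blocks:
        return mean, float("nan")
    usable = (len(x) // n_blocks) * n_blocks
    blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    se = float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))
    return mean, se


def surface_tension(series: PressureTensorSeries,
                    n_blocks: int = 5) -> tuple[float, float]:
    """Surface (or interfacial) tension in mN/m with a block-averaged SE.

    gamma = L_Z/2 * (P_Z - (P_X + P_Y)/2), bar*nm converted by the factor
    0.1 mN/m per bar*nm.  The estimator is linear in the pressure
    anisotropy, so an isotropic series gives exactly zero.
    """
    if len(series.time) < 2:
        raise ValueError("need at least two samples for an error estimate")
    aniso = series.p_z - 0.5 * (series.p_x + series.p_y)
    gamma_t = 0.5 * series.box_lz * aniso * BAR_NM_TO_MN_PER_M
    return _block_mean_se(gamma_t, n_blocks)


def normal_pressure(series: PressureTensorSeries,
                    n_blocks: int = 5) -> tuple[float, float]:
    """Mean and block SE of the pressure normal to the slab, bar."""
    return _block_mean_se(series.p_z, n_blocks)
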