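"""Critical-point, vapor-pressure and free-energy thermodynamics.

Coexistence densities are extrapolated to the critical point with a Wegner
expansion of the density difference,

    rho_l - rho_g = sum_k A_k |tau|^(beta_c + k*Delta),    tau = 1 - T/T_C,

with the 3D-Ising exponents beta_c = 0.325 and Delta = 0.5 held fixed, and a
rectilinear-diameter law with a |tau|^(1-alpha') correction (alpha' = 0.11)
for the critical density.  Vapor pressures follow the Antoine form
ln P = A + B/(T + C), fitted by least squares on ln P over a stated
temperature window.  The boiling point is obtained either by inverting an
Antoine fit at the threshold pressure, or by the free-energy route: vapor
pressures reconstructed from (Delta G_vap, rho_l) via the ideal-gas relation
are correlated linearly against 1/T (Gibbs-Helmholtz) and the 1-atm crossing
solved for.  Solubility bookkeeping sums Delta G_vap and Delta G_hyd with
uncertainties combined in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .constants import (
    ATM_BAR,
    KB_J_PER_K,
    M_CYCLOHEXENE,
    P_STANDARD_PA,
    R_J_PER_MOL_K,
    R_KJ_PER_MOL_K,
)

BETA_C = 0.325   # 3D Ising order-parameter exponent
DELTA = 0.5      # first Wegner correction exponent
ALPHA_PRIME = 0.11  # rectilinear-diameter correction exponent


@dataclass
class PhysicalConstants:
    R: float = R_J_PER_MOL_K                 # J/(mol K)
    k_B: float = KB_J_PER_K                  # J/K
    p_standard: float = P_STANDARD_PA        # Pa (1 atm)
    molar_mass: float = M_CYCLOHEXENE        # g/mol


CONSTANTS = PhysicalConstants()


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

@dataclass
class CoexistenceCurve:
    """Liquid and vapor densities along liquid-vapor equilibrium."""

    T: np.ndarray       # K, strictly increasing
    rho_l: np.ndarray   # g/L
    rho_g: np.ndarray   # g/L

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.rho_l = np.asarray(self.rho_l, dtype=float)
        self.rho_g = np.asarray(self.rho_g, dtype=float)
        if not (len(self.T) == len(self.rho_l) == len(self.rho_g)):
            raise ValueError("curve columns must align")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.rho_g <= 0) or np.any(self.rho_l <= self.rho_g):
            raise ValueError("require rho_l > rho_g > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T_K": self.T, "rho_l_g_per_L": self.rho_l,
                             "rho_g_g_per_L": self.rho_g})


@dataclass
class VaporPressureCurve:
    T: np.ndarray   # K
    P: np.ndarray   # bar

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if len(self.T) != len(self.P):
            raise ValueError("curve columns must align")
        if np.any(self.P <= 0):
            raise ValueError("pressures must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T_K": self.T, "P_bar": self.P})


# ---------------------------------------------------------------------------
# Wegner / rectilinear critical-point fits
# ---------------------------------------------------------------------------

@dataclass
class WegnerFit:
    T_C: float                  # K
    amplitudes: np.ndarray      # A0..A3, g/L
    beta_c: float = BETA_C
    delta: float = DELTA
    residual_norm: float = 0.0

    def difference(self, T: np.ndarray) -> np.ndarray:
        tau = np.abs(1.0 - np.asarray(T, dtype=float) / self.T_C)
        exps = self.beta_c + self.delta * np.arange(len(self.amplitudes))
        return (tau[..., None] ** exps) @ self.amplitudes


@dataclass
class RectilinearFit:
    rho_c: float                # g/L
    D_1ma: float                # coefficient of |tau|^(1-alpha')
    D_1: float                  # coefficient of |tau|
    alpha_prime: float = ALPHA_PRIME
    residual_norm: float = 0.0

    def total(self, T: np.ndarray, T_C: float) -> np.ndarray:
        tau = np.abs(1.0 - np.asarray(T, dtype=float) / T_C)
        return 2 * self.rho_c + self.D_1ma * tau ** (1 - self.alpha_prime) \
            + self.D_1 * tau


def _wegner_design(T: np.ndarray, T_C: float, n_terms: int) -> np.ndarray:
    tau = np.abs(1.0 - T / T_C)
    exps = BETA_C + DELTA * np.arange(n_terms)
    return tau[:, None] ** exps


def fit_wegner(curve: CoexistenceCurve, n_terms: int = 4,
               bracket: tuple[float, float] | None = None) -> WegnerFit:
    """Fit rho_l - rho_g; amplitudes are linear given T_C, T_C by bounded
    1-D search (default bracket: max data T + 1 K .. + 300 K)."""
    T = curve.T
    y = curve.rho_l - curve.rho_g
    if len(T) < n_terms + 1:
        raise ValueError(f"need at least {n_terms + 1} rows for {n_terms + 1} "
                         "free parameters")
    if bracket is None:
        bracket = (float(T.max()) + 1.0, float(T.max()) + 300.0)

    def sse(tc: float) -> float:
        X = _wegner_design(T, tc, n_terms)
        amps, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = X @ amps - y
        return float(r @ r)

    res = minimize_scalar(sse, bounds=bracket, method="bounded",
                          options={"xatol": 1e-6})
    tc = float(res.x)
    span = bracket[1] - bracket[0]
    if min(tc - bracket[0], bracket[1] - tc) < 1e-3 * span:
        raise ValueError(f"best T_C = {tc:.2f} K sits at the search bound "
                         f"{bracket}")
    X = _wegner_design(T, tc, n_terms)
    amps, *_ = np.linalg.lstsq(X, y, rcond=None)
    return WegnerFit(T_C=tc, amplitudes=amps,
                     residual_norm=float(np.linalg.norm(X @ amps - y)))


def fit_rectilinear(curve: CoexistenceCurve, T_C: float) -> RectilinearFit:
    """Linear fit of rho_l + rho_g on {1, |tau|^(1-alpha'), |tau|};
    rho_C = intercept / 2."""
    if len(curve.T) < 3:
        raise ValueError("need at least 3 rows")
    tau = np.abs(1.0 - curve.T / T_C)
    X = np.column_stack([np.ones_like(tau), tau ** (1 - ALPHA_PRIME), tau])
    y = curve.rho_l + curve.rho_g
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("degenerate rectilinear design (collinear columns)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return RectilinearFit(rho_c=float(coef[0] / 2), D_1ma=float(coef[1]),
                          D_1=float(coef[2]),
                          residual_norm=float(np.linalg.norm(X @ coef - y)))


# ---------------------------------------------------------------------------
# Antoine vapor-pressure fits
# ---------------------------------------------------------------------------

@dataclass
class AntoineFit:
    """ln(P) = A + B/(T + C); P in ``pressure_unit`` over [T_min, T_max]."""

    A: float
    B: float          # K
    C: float          # K
    T_min: float
    T_max: float
    pressure_unit: str = "bar"
    residual_norm: float = 0.0


def antoine_eval(fit: AntoineFit, T) -> np.ndarray | float:
    T = np.asarray(T, dtype=float)
    if np.any(T + fit.C <= 0):
        raise ValueError("T + C must be positive")
    out = np.exp(fit.A + fit.B / (T + fit.C))
    return float(out) if out.ndim == 0 else out


def antoine_invert(fit: AntoineFit, P: float) -> float:
    """Temperature at which the fitted vapor pressure equals ``P``."""
    lnp = np.log(P)
    if abs(lnp - fit.A) < 1e-300:
        raise ZeroDivisionError("ln(P) equals the Antoine A parameter")
    T = fit.B / (lnp - fit.A) - fit.C
    if T + fit.C <= 0:
        raise ValueError("inversion leaves the valid domain (T + C <= 0)")
    return float(T)


def fit_antoine(vp: VaporPressureCurve,
                T_range: tuple[float, float] | None = None,
                pressure_unit: str = "bar") -> AntoineFit:
    """Least squares on ln(P): A, B linear given C, C by bounded search."""
    if T_range is None:
        T_range = (float(vp.T.min()), float(vp.T.max()))
    sel = (vp.T >= T_range[0]) & (vp.T <= T_range[1])
    T = vp.T[sel]
    lnp = np.log(vp.P[sel])
    if len(T) < 3:
        raise ValueError("need at least 3 in-range rows")

    def sse(c: float) -> float:
        X = np.column_stack([np.ones_like(T), 1.0 / (T + c)])
        coef, *_ = np.linalg.lstsq(X, lnp, rcond=None)
        r = X @ coef - lnp
        return float(r @ r)

    lo = -float(T.min()) + 1.0
    res = minimize_scalar(sse, bounds=(lo, 500.0), method="bounded",
                          options={"xatol": 1e-9})
    c = float(res.x)
    X = np.column_stack([np.ones_like(T), 1.0 / (T + c)])
    coef, *_ = np.linalg.lstsq(X, lnp, rcond=None)
    return AntoineFit(A=float(coef[0]), B=float(coef[1]), C=c,
                      T_min=T_range[0], T_max=T_range[1],
                      pressure_unit=pressure_unit,
                      residual_norm=float(np.linalg.norm(X @ coef - lnp)))


def critical_pressure(fit: AntoineFit, T_C: float) -> float:
    """Antoine evaluation at the critical temperature (warns when
    extrapolating past the fit window)."""
    if T_C > fit.T_max or T_C < fit.T_min:
        warnings.warn(
            f"T_C = {T_C:.1f} K lies outside the Antoine window "
            f"[{fit.T_min:.0f}, {fit.T_max:.0f}] K; extrapolating",
            RuntimeWarning,
        )
    return float(antoine_eval(fit, T_C))


# ---------------------------------------------------------------------------
# Free-energy route: Delta G_vap, vapor pressure, boiling point
# ---------------------------------------------------------------------------

def dgvap_from_densities(rho_g: float, rho_l: float, T: float) -> float:
    """Delta G_vap = -RT ln(rho_g / rho_l), kJ/mol (densities in g/L)."""
    if rho_g <= 0 or rho_l <= 0:
        raise ValueError("densities must be positive")
    return float(-R_KJ_PER_MOL_K * T * np.log(rho_g / rho_l))


def vapor_pressure_from_dgvap(dgvap: float, rho_l: float, T: float,
                              constants: PhysicalConstants = CONSTANTS
                              ) -> float:
    """Vapor pressure (bar) from Delta G_vap (kJ/mol) and liquid density
    (g/L), assuming ideal-gas vapor:

        ln(P_g/P0) = ln(R T rho_l / (M P0)) - Delta G_vap / (R T)
    """
    if rho_l <= 0:
        raise ValueError("liquid density must be positive")
    c_molar = rho_l / constants.molar_mass * 1000.0  # mol/m^3
    ln_ratio = np.log(constants.R * T * c_molar / constants.p_standard) \
        - dgvap * 1000.0 / (constants.R * T)
    return float(np.exp(ln_ratio) * constants.p_standard / 1e5)


@dataclass
class FreeEnergyVapPoint:
    T: float        # K
    dgvap: float    # kJ/mol
    rho_l: float    # g/L


def boiling_point_free_energy(points: list[FreeEnergyVapPoint],
                              threshold_bar: float = ATM_BAR,
                              constants: PhysicalConstants = CONSTANTS
                              ) -> float:
    """Boiling point from the free-energy method.

    ln(P_g/P_threshold) per point is correlated linearly against 1/T
    (Gibbs-Helmholtz); the returned temperature is where the line crosses
    zero, i.e. where the reconstructed vapor pressure reaches the threshold
    (1 atm by default, switchable to 1 bar).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    T = np.array([p.T for p in points])
    if len(np.unique(T)) < 2:
        raise ValueError("degenerate fit: points share a temperature")
    lnp = np.array([
        np.log(vapor_pressure_from_dgvap(p.dgvap, p.rho_l, p.T, constants)
               / threshold_bar)
        for p in points
    ])
    slope, intercept = np.polyfit(1.0 / T, lnp, 1)
    if slope == 0:
        raise ValueError("no crossing: zero slope in ln P vs 1/T")
    inv_tb = -intercept / slope
    if inv_tb <= 0:
        raise ValueError("no physical crossing (1/T <= 0)")
    return float(1.0 / inv_tb)


# ---------------------------------------------------------------------------
# Auxiliary property estimators
# ---------------------------------------------------------------------------

def stokes_einstein_radius(D: float, eta: float, T: float) -> float:
    """Hydrodynamic radius r = k_B T / (6 pi eta D) in Angstrom.

    D in cm^2/s, eta in mPa*s, T in K.
    """
    if D <= 0 or eta <= 0 or T <= 0:
        raise ValueError("D, eta and T must be positive")
    r_m = KB_J_PER_K * T / (6 * np.pi * (eta * 1e-3) * (D * 1e-4))
    return float(r_m * 1e10)


def solvation_free_energy(dgvap: float, dghyd: float,
                          dgvap_err: float = 0.0, dghyd_err: float = 0.0
                          ) -> tuple[float, float]:
    """Delta G_sol = Delta G_vap + Delta G_hyd; uncertainty in quadrature."""
    return (float(dgvap + dghyd),
            float(np.hypot(dgvap_err, dghyd_err)))


def enthalpy_of_vaporization(u_gas: float, u_liq: float, T: float) -> float:
    """Delta H_vap = U_gas - U_liq + RT, kJ/mol (per-molecule energies in
    kJ/mol)."""
    return float(u_gas - u_liq + R_KJ_PER_MOL_K * T)


def isothermal_compressibility(volumes: np.ndarray, T: float) -> float:
    """kappa_T = <dV^2> / (k_B T <V>) from an NPT volume series.

    Volumes in nm^3; returns MPa^-1.
    """
    v = np.asarray(volumes, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 volume samples")
    var = float(np.var(v))          # nm^6
    mean = float(np.mean(v))        # nm^3
    kappa_per_pa = (var / mean) * 1e-27 / (KB_J_PER_K * T)
    return kappa_per_pa * 1e6       # MPa^-1


# ---------------------------------------------------------------------------
# Property table (the final report container)
# ---------------------------------------------------------------------------

@dataclass
class PropertyEstimate:
    value: float
    sigma: float | None
    units: str
    model: str    # one of N / H / M

    def as_dict(self) -> dict:
        return {"value": self.value, "sigma": self.sigma,
                "units": self.units, "model": self.model}


UNIT_REGISTRY = {
    "density": "g/L",
    "critical_density": "g/L",
    "critical_temperature": "K",
    "critical_pressure": "bar",
    "boiling_point_antoine": "K",
    "boiling_point_free_energy": "K",
    "surface_tension": "mN/m",
    "interfacial_tension": "mN/m",
    "vaporization_free_energy": "kJ/mol",
    "hydration_free_energy": "kJ/mol",
    "solvation_free_energy": "kJ/mol",
    "vaporization_enthalpy": "kJ/mol",
    "isothermal_compressibility": "1/MPa",
    "diffusion_constant_hydrated": "cm^2/s",
    "diffusion_constant_pure": "cm^2/s",
    "viscosity": "mPa*s",
    "hydrodynamic_radius": "A",
}


@dataclass
class PropertyTable:
    entries: dict[str, PropertyEstimate] = field(default_factory=dict)

    def add(self, name: str, value: float, sigma: float | None,
            model: str, units: str | None = None) -> None:
        if units is None:
            if name not in UNIT_REGISTRY:
                raise KeyError(f"unknown property {name!r}; give units explicitly")
            units = UNIT_REGISTRY[name]
        elif name in UNIT_REGISTRY and units != UNIT_REGISTRY[name]:
            raise ValueError(
                f"units {units!r} for {name!r} contradict the registry "
                f"({UNIT_REGISTRY[name]!r})"
            )
        if model not in ("N", "H", "M"):
            raise ValueError("model tag must be N, H or M")
        self.entries[name] = PropertyEstimate(value, sigma, units, model)

    def as_dict(self) -> dict:
        return {k: v.as_dict() for k, v in self.entries.items()}

    def to_text(self) -> str:
        lines = [f"{'property':<34}{'model':<7}{'estimate':>14}"
                 f"{'1-sigma':>12}  units"]
        for name, e in self.entries.items():
            sig = f"{e.sigma:.4g}" if e.sigma is not None else "-"
            lines.append(f"{name:<34}{e.model:<7}{e.value:>14.6g}"
                         f"{sig:>12}  {e.units}")
        return "\n".join(lines)
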