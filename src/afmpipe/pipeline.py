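"""End-to-end analysis pipeline on the synthetic scenario.

``run_pipeline`` strings the stages together — force-field fitting, slab
observables, critical point, Antoine fits, boiling point, transport,
solubility — on seeded synthetic inputs with known ground truth, and emits a
property table with 1-sigma uncertainties plus a provenance block.  Re-running
with an identical configuration and seed reproduces the report bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import ATM_BAR, P_STANDARD_PA, R_J_PER_MOL_K
from . import io as afio
from . import synthetic as syn
from .force_matching import compute_fit_metrics, get_param, set_param, staged_fit, default_stages
from .model_core import NEAT_SCHEME
from .slab import coexistence_densities, density_profile, surface_tension
from .thermo import (
    FreeEnergyVapPoint,
    PropertyTable,
    antoine_invert,
    boiling_point_free_energy,
    critical_pressure,
    fit_antoine,
    fit_rectilinear,
    fit_wegner,
    isothermal_compressibility,
    solvation_free_energy,
    stokes_einstein_radius,
    vapor_pressure_from_dgvap,
)
from .transport import diffusion_from_msd, msd_from_trajectory, viscosity_green_kubo

logger = logging.getLogger("afmpipe")

ALL_STAGES = ("fit", "slab", "critical", "antoine", "boil", "transport",
              "solubility", "report")


class ConfigError(ValueError):
    """Bad run configuration (unknown key, invalid value)."""


class PipelineError(RuntimeError):
    """A stage cannot run (missing upstream artifact or data problem)."""


@dataclass
class RunConfig:
    """Resolved pipeline configuration; unknown keys are rejected.

    All tunables with a bearing on the estimators are surfaced here:
    objective weights, slab thresholds, block counts, the boiling-point
    pressure convention and the two Antoine temperature windows.
    """

    seed: int = 1
    stages: tuple = ALL_STAGES
    outdir: str | None = None
    # force-matching stage
    fm_n_configs: int = 6
    fm_n_molecules: int = 4
    fm_noise_sigma: float = 0.0
    fm_cutoff: float = 12.0
    fm_start_perturbation: float = 0.05
    w_atomic: float = 1.0
    w_molforce: float = 1.0
    w_torque: float = 1.0
    torque_lever: float = 1.0
    ridge: float = 0.0
    regression_through_origin: bool = True
    # slab stage
    gamma_true: float = syn.DEFAULT_GAMMA_MN_M
    box_lz_nm: float = syn.DEFAULT_LZ_NM
    slab_rho_l: float = 800.0
    slab_rho_g: float = 5.0
    slab_frames: int = 60
    interface_threshold: float = 0.5
    core_fraction: float = 0.5
    vapor_buffer_nm: float = 1.0
    n_blocks: int = 5
    # critical stage
    tc_true: float = syn.DEFAULT_TC_K
    rhoc_true: float = syn.DEFAULT_RHOC_G_L
    coex_noise_rel: float = 0.0
    antoine_window_low: tuple = (360.0, 440.0)
    antoine_window_high: tuple = (380.0, 460.0)
    # boiling stage
    tb_threshold: str = "atm"  # "atm" or "bar"
    fe_temperatures: tuple = syn.DEFAULT_FREE_ENERGY_TEMPS
    rho_l_ref: float = 811.0       # g/L at 298.15 K
    rho_l_slope: float = -0.95     # g/(L K)
    # transport stage
    d_true: float = syn.DEFAULT_D_CM2_S   # hydrated-phase diffusion truth
    d_pure_true: float = 1.9e-5           # pure-phase diffusion truth
    brownian_particles: int = 200
    brownian_steps: int = 4000
    eta_true: float = 0.66
    stress_samples: int = 100000
    kappa_t_true: float = syn.DEFAULT_KAPPA_T_MPA
    volume_samples: int = 100000
    temperature: float = 298.15
    # solubility stage
    dgvap_kj_mol: float = 18.2
    dgvap_err: float = 0.2
    dghyd_kj_mol: float = 3.8
    dghyd_err: float = 0.3

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()})
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}; valid: {list(ALL_STAGES)}")
        if cfg.tb_threshold not in ("atm", "bar"):
            raise ConfigError("tb_threshold must be 'atm' or 'bar'")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(doc)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        for k in ("antoine_window_low", "antoine_window_high", "fe_temperatures"):
            d[k] = list(d[k])
        return d


@dataclass
class Report:
    properties: PropertyTable = field(default_factory=PropertyTable)
    fit_metrics: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "properties": self.properties.as_dict(),
            "fit_metrics": self.fit_metrics,
            "extras": self.extras,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)


def _log_stage(name: str, t0: float, inputs_hash: str) -> None:
    logger.info("stage=%s inputs=%s elapsed=%.2fs",
                name, inputs_hash, time.perf_counter() - t0)


def _threshold_bar(config: RunConfig) -> float:
    return ATM_BAR if config.tb_threshold == "atm" else 1.0


def _rho_l_model(config: RunConfig, T: float) -> float:
    return config.rho_l_ref + config.rho_l_slope * (T - 298.15)


def _dgvap_from_truth(config: RunConfig, T: float) -> float:
    """Invert the ideal-gas vapor-pressure relation on the Antoine truth to
    get the Delta G_vap a simulation at T would have produced."""
    from .thermo import antoine_eval
    p_bar = antoine_eval(syn.DEFAULT_ANTOINE, T)
    rho_l = _rho_l_model(config, T)
    # ln(P/P0) = ln(R T c / P0) - dG/(R T)  =>  dG = R T [ln(R T c / P0) - ln(P/P0)]
    from .constants import M_CYCLOHEXENE
    c = rho_l / M_CYCLOHEXENE * 1000.0  # mol/m^3
    ln_c_term = np.log(R_J_PER_MOL_K * T * c / P_STANDARD_PA)
    ln_p = np.log(p_bar * 1e5 / P_STANDARD_PA)
    return float(R_J_PER_MOL_K * T * (ln_c_term - ln_p) / 1000.0)  # kJ/mol


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_fit(config: RunConfig, report: Report) -> None:
    t0 = time.perf_counter()
    records, manifest = syn.gen_training_set(
        config.seed, phase="neat", n_configs=config.fm_n_configs,
        n_molecules=config.fm_n_molecules, noise_sigma=config.fm_noise_sigma,
        cutoff=config.fm_cutoff,
    )
    truth = syn.ground_truth_params(NEAT_SCHEME)
    start = truth.copy()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    stages = default_stages(records, set().union(*[set(k) for k in truth.pairs]),
                            start, cutoff=config.fm_cutoff)
    for st in stages:
        st.ridge = config.ridge
        st.torque_lever = config.torque_lever
        for key in st.free:
            v = get_param(start, key)
            if v != 0.0:
                set_param(start, key,
                          v * (1 + rng.uniform(-config.fm_start_perturbation,
                                               config.fm_start_perturbation)))
    fitted = staged_fit(start, records, stages, cutoff=config.fm_cutoff)
    metrics = compute_fit_metrics(fitted, records, cutoff=config.fm_cutoff,
                                  through_origin=config.regression_through_origin)
    free_keys = [k for st in stages for k in st.free]
    rel_err = max(
        abs(get_param(fitted, k) - get_param(truth, k))
        / max(abs(get_param(truth, k)), 1e-12)
        for k in free_keys
    )
    report.fit_metrics = {
        cls: {"rmse": m.rmse, "slope": m.slope, "r2": m.r2}
        for cls, m in metrics.items()
    }
    report.extras["fit_max_param_rel_error"] = rel_err
    report.extras["fit_manifest"] = manifest
    _log_stage("fit", t0, afio.data_hash(manifest))


def _stage_slab(config: RunConfig, report: Report) -> None:
    t0 = time.perf_counter()
    series, man_p = syn.gen_pressure_series(
        config.seed, gamma_true=config.gamma_true, box_lz=config.box_lz_nm)
    gamma, gamma_se = surface_tension(series, n_blocks=config.n_blocks)
    report.properties.add("surface_tension", gamma, gamma_se, "M")
    frames, man_s = syn.gen_slab_frames(
        config.seed, rho_l=config.slab_rho_l, rho_g=config.slab_rho_g,
        n_frames=config.slab_frames)
    profile = density_profile(frames, axis=2, n_bins=100)
    rho_l, rho_g = coexistence_densities(
        profile, config.interface_threshold, config.core_fraction,
        config.vapor_buffer_nm)
    report.properties.add("density", rho_l, None, "N")
    report.extras["slab_rho_g_g_per_L"] = rho_g
    report.extras["slab_manifests"] = [man_p, man_s]
    _log_stage("slab", t0, afio.data_hash([man_p, man_s]))


def _stage_critical(config: RunConfig, report: Report, artifacts: dict) -> None:
    t0 = time.perf_counter()
    curve, man_c = syn.gen_coexistence_curve(
        config.seed, T_C=config.tc_true, rho_c=config.rhoc_true,
        noise_rel=config.coex_noise_rel)
    wfit = fit_wegner(curve)
    rfit = fit_rectilinear(curve, wfit.T_C)
    report.properties.add("critical_temperature", wfit.T_C, None, "N")
    report.properties.add("critical_density", rfit.rho_c, None, "N")
    temps_high = np.linspace(*config.antoine_window_high, 6)
    vp_high, man_v = syn.gen_vapor_pressure_curve(config.seed,
                                                  temperatures=temps_high)
    afit_high = fit_antoine(vp_high, config.antoine_window_high)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_c = critical_pressure(afit_high, wfit.T_C)
    report.properties.add("critical_pressure", p_c, None, "N")
    artifacts["vapor_pressure_curve"] = vp_high
    artifacts["antoine_high"] = afit_high
    report.extras["critical_manifests"] = [man_c, man_v]
    report.extras["wegner_amplitudes_g_per_L"] = [float(a) for a in wfit.amplitudes]
    _log_stage("critical", t0, afio.data_hash([man_c, man_v]))


def _stage_antoine(config: RunConfig, report: Report, artifacts: dict) -> None:
    t0 = time.perf_counter()
    temps_low = np.linspace(*config.antoine_window_low, 6)
    vp_low, man = syn.gen_vapor_pressure_curve(config.seed,
                                               temperatures=temps_low)
    afit_low = fit_antoine(vp_low, config.antoine_window_low)
    artifacts["antoine_low"] = afit_low
    tb = antoine_invert(afit_low, _threshold_bar(config))
    report.properties.add("boiling_point_antoine", tb, None, "N")
    report.extras["antoine_low"] = {"A": afit_low.A, "B": afit_low.B,
                                    "C": afit_low.C}
    _log_stage("antoine", t0, afio.data_hash(man))


def _stage_boil(config: RunConfig, report: Report, artifacts: dict) -> None:
    t0 = time.perf_counter()
    points = [
        FreeEnergyVapPoint(T=T, dgvap=_dgvap_from_truth(config, T),
                           rho_l=_rho_l_model(config, T))
        for T in config.fe_temperatures
    ]
    tb_fe = boiling_point_free_energy(points,
                                      threshold_bar=_threshold_bar(config))
    report.properties.add("boiling_point_free_energy", tb_fe, None, "N")
    dg298 = points[0].dgvap
    report.properties.add("vaporization_free_energy", dg298, None, "N")
    p298 = vapor_pressure_from_dgvap(dg298, points[0].rho_l, points[0].T)
    report.extras["vapor_pressure_298_bar"] = p298
    _log_stage("boil", t0, afio.data_hash([p.T for p in points]))


def _stage_transport(config: RunConfig, report: Report) -> None:
    t0 = time.perf_counter()
    traj, man_b = syn.gen_brownian(config.seed, D_true=config.d_true,
                                   n_particles=config.brownian_particles,
                                   n_steps=config.brownian_steps)
    msd = msd_from_trajectory(traj, dt=1.0)
    d_est, d_se = diffusion_from_msd(msd)
    report.properties.add("diffusion_constant_hydrated", d_est, d_se, "H")
    traj_p, man_p = syn.gen_brownian(config.seed, D_true=config.d_pure_true,
                                     n_particles=config.brownian_particles,
                                     n_steps=config.brownian_steps,
                                     stream="brownian_pure")
    d_p, d_p_se = diffusion_from_msd(msd_from_trajectory(traj_p, dt=1.0))
    report.properties.add("diffusion_constant_pure", d_p, d_p_se, "M")
    stress, man_s = syn.gen_stress_series(config.seed, eta_true=config.eta_true,
                                          T=config.temperature,
                                          n=config.stress_samples)
    max_lag = min(2000, config.stress_samples // 10)
    eta, eta_se = viscosity_green_kubo(stress, max_lag)
    report.properties.add("viscosity", eta, eta_se, "M")
    vols, man_v = syn.gen_volume_series(config.seed,
                                        kappa_t=config.kappa_t_true,
                                        T=config.temperature,
                                        n=config.volume_samples)
    kappa = isothermal_compressibility(vols, config.temperature)
    report.properties.add("isothermal_compressibility", kappa, None, "N")
    radius = stokes_einstein_radius(d_p, eta, config.temperature)
    report.properties.add("hydrodynamic_radius", radius, None, "M")
    report.extras["transport_manifests"] = [man_b, man_p, man_s, man_v]
    _log_stage("transport", t0, afio.data_hash([man_b, man_s, man_v]))


def _stage_solubility(config: RunConfig, report: Report) -> None:
    t0 = time.perf_counter()
    dg_sol, dg_err = solvation_free_energy(
        config.dgvap_kj_mol, config.dghyd_kj_mol,
        config.dgvap_err, config.dghyd_err)
    report.properties.add("solvation_free_energy", dg_sol, dg_err, "M")
    _log_stage("solubility", t0,
               afio.data_hash([config.dgvap_kj_mol, config.dghyd_kj_mol]))


def _stage_report(config: RunConfig, report: Report) -> None:
    if config.outdir is None:
        return
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "report.txt").write_text(report.properties.to_text() + "\n")


def run_pipeline(config: RunConfig) -> Report:
    """Execute the selected stages in dependency order and return the
    property report."""
    report = Report()
    report.provenance = {
        "config": config.as_dict(),
        "config_hash": afio.data_hash(config.as_dict()),
        "seed": config.seed,
    }
    selected = [s for s in ALL_STAGES if s in config.stages]
    artifacts: dict = {}
    for stage in selected:
        try:
            if stage == "fit":
                _stage_fit(config, report)
            elif stage == "slab":
                _stage_slab(config, report)
            elif stage == "critical":
                _stage_critical(config, report, artifacts)
            elif stage == "antoine":
                _stage_antoine(config, report, artifacts)
            elif stage == "boil":
                _stage_boil(config, report, artifacts)
            elif stage == "transport":
                _stage_transport(config, report)
            elif stage == "solubility":
                _stage_solubility(config, report)
            elif stage == "report":
                _stage_report(config, report)
        except PipelineError:
            raise
        except (ValueError, KeyError) as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return report
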