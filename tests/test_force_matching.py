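"""Staged force-matching: residuals, linear/nonlinear recovery, the
mixed-phase joint fit and fit-quality metrics."""

import numpy as np
import pytest

from afmpipe.force_matching import (
    FitStage,
    SingularFitError,
    TrainingRecord,
    compute_fit_metrics,
    default_stages,
    fit_hydrated,
    fit_stage,
    fm_residuals,
    get_param,
    joint_mixed_phase_fit,
    regression_metrics,
    set_param,
    staged_fit,
    validate_stage_spec,
)
from afmpipe.model_core import (
    Configuration,
    ForceFieldParams,
    HYDRATED_SCHEME,
    PairParams,
    evaluate_energy_forces,
    molecular_force_torque,
)
from afmpipe.synthetic import SOLVENT_TYPES, gen_training_set, ground_truth_params

from conftest import HYDRATED_TYPES, NEAT_TYPES, perturbed_params


# ---------------------------------------------------------------------------
# Residuals
# ---------------------------------------------------------------------------

def test_residuals_vanish_when_model_equals_reference(neat_records_small,
                                                      neat_truth):
    stage = FitStage("all", [], w_atomic=1, w_molforce=1, w_torque=1)
    r = fm_residuals(neat_truth, neat_records_small, stage)
    assert np.abs(r).max() < 1e-10


def test_residual_weighting_is_sqrt_of_weight():
    cfg = Configuration(coords=np.zeros((1, 3)), elements=["C"],
                        molecule_id=np.array([0]), type_labels=["X"])
    params = ForceFieldParams(pairs={("X", "X"): PairParams(A=0.0, b=1.0)},
                              charges_enabled=False)
    ref = np.array([[-1.0, 0.0, 0.0]])  # model force is zero
    rec = TrainingRecord(configuration=cfg, reference_forces=ref)
    stage = FitStage("atomic", [], w_atomic=4.0, w_molforce=0.0, w_torque=0.0)
    r = fm_residuals(params, [rec], stage)
    assert np.allclose(r, [2.0, 0.0, 0.0])


def test_residual_norm_matches_brute_force_sum(neat_records_small, neat_truth):
    """||residual||^2 equals the directly summed weighted squared errors."""
    params = perturbed_params(
        neat_truth, [("A", k) for k in neat_truth.pairs],
        np.random.default_rng(0), 0.2)
    stage = FitStage("all", [], w_atomic=1.3, w_molforce=0.7, w_torque=2.0,
                     torque_lever=1.0)
    r = fm_residuals(params, neat_records_small, stage)
    brute = 0.0
    for rec in neat_records_small:
        cfg = rec.configuration
        _, model = evaluate_energy_forces(cfg, params, 12.0)
        diff = model.forces - rec.reference_forces
        brute += 1.3 * np.sum(diff[rec.mask] ** 2)
        nets_m, tq_m = molecular_force_torque(model, cfg)
        from afmpipe.model_core import ForceRecord
        nets_r, tq_r = molecular_force_torque(
            ForceRecord(rec.reference_forces), cfg)
        brute += 0.7 * np.sum((nets_m - nets_r) ** 2)
        brute += 2.0 * np.sum((tq_m - tq_r) ** 2)
    assert np.dot(r, r) == pytest.approx(brute, rel=1e-10)


def test_empty_training_set_rejected(neat_truth):
    stage = FitStage("x", [])
    with pytest.raises(ValueError):
        fm_residuals(neat_truth, [], stage)


# ---------------------------------------------------------------------------
# Stage validation
# ---------------------------------------------------------------------------

def test_stage_spec_keeps_dispersion_frozen(neat_truth):
    key = next(iter(neat_truth.pairs))
    with pytest.raises(ValueError, match="dispersion"):
        validate_stage_spec([FitStage("bad", [("C6", key)])], neat_truth)


def test_stage_spec_orders_intermolecular_first(neat_truth):
    key = next(iter(neat_truth.pairs))
    bkey = next(iter(neat_truth.bonds))
    stages = [FitStage("intra", [("bond_k", bkey)]),
              FitStage("inter", [("A", key)])]
    with pytest.raises(ValueError, match="intermolecular"):
        validate_stage_spec(stages, neat_truth)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def test_linear_parameters_recovered_exactly(neat_records_small, neat_truth):
    """Zero noise, only linear parameters free: recovery to <= 1e-6."""
    rng = np.random.default_rng(2)
    keys = [("A", k) for k in sorted(neat_truth.pairs)] \
        + [("bond_k", k) for k in sorted(neat_truth.bonds)]
    start = perturbed_params(neat_truth, keys, rng, 0.3)
    stage = FitStage("linear", keys, w_atomic=1.0, w_molforce=1.0, w_torque=1.0)
    fitted = fit_stage(start, neat_records_small, stage)
    for k in keys:
        assert get_param(fitted, k) == pytest.approx(
            get_param(neat_truth, k), rel=1e-6)


def test_buckingham_decay_recovered_from_perturbed_start(neat_records_small,
                                                         neat_truth):
    """b free alongside A: recovery to <= 1e-3 from a start within 20%."""
    rng = np.random.default_rng(3)
    keys = [(kind, k) for k in sorted(neat_truth.pairs) for kind in ("A", "b")]
    start = perturbed_params(neat_truth, keys, rng, 0.2)
    stage = FitStage("inter", keys, w_atomic=0.0, w_molforce=1.0, w_torque=1.0)
    fitted = fit_stage(start, neat_records_small, stage)
    for k in keys:
        assert get_param(fitted, k) == pytest.approx(
            get_param(neat_truth, k), rel=1e-3)


def test_gaussian_noise_leaves_linear_estimates_unbiased(neat_truth):
    """Mean recovery error of linear parameters over 20 noisy replicates is
    within 2 standard errors of zero."""
    keys = [("A", k) for k in sorted(neat_truth.pairs)]
    stage = FitStage("lin", keys, w_atomic=1.0, w_molforce=0.0, w_torque=0.0)
    errors = {k: [] for k in keys}
    for seed in range(20):
        records, _ = gen_training_set(seed=seed, phase="neat", n_configs=3,
                                      n_molecules=3, noise_sigma=1.0)
        start = perturbed_params(neat_truth, keys,
                                 np.random.default_rng(seed), 0.2)
        fitted = fit_stage(start, records, stage)
        for k in keys:
            errors[k].append(get_param(fitted, k) - get_param(neat_truth, k))
    for k, errs in errors.items():
        errs = np.array(errs)
        se = errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean()) < 2.5 * se + 1e-9, k


def test_full_staged_fit_objective_never_increases(neat_records_small,
                                                   neat_truth):
    rng = np.random.default_rng(4)
    stages = default_stages(neat_records_small, NEAT_TYPES, neat_truth)
    start = perturbed_params(
        neat_truth, [k for st in stages for k in st.free], rng, 0.1)
    current = start
    for st in stages:
        before = float(np.sum(fm_residuals(current, neat_records_small, st) ** 2))
        current = fit_stage(current, neat_records_small, st)
        after = float(np.sum(fm_residuals(current, neat_records_small, st) ** 2))
        assert after <= before * (1 + 1e-12)


def test_fitted_rmse_not_worse_than_initial_guess(neat_truth):
    records, _ = gen_training_set(seed=31, phase="neat", n_configs=3,
                                  n_molecules=3, noise_sigma=0.5)
    rng = np.random.default_rng(5)
    keys = [("A", k) for k in sorted(neat_truth.pairs)]
    start = perturbed_params(neat_truth, keys, rng, 0.3)
    stage = FitStage("lin", keys, w_atomic=1.0, w_molforce=0.0, w_torque=0.0)
    fitted = fit_stage(start, records, stage)
    rmse_start = compute_fit_metrics(start, records)["atomic_force"].rmse
    rmse_fit = compute_fit_metrics(fitted, records)["atomic_force"].rmse
    assert rmse_fit <= rmse_start


def test_singular_fit_names_unconstrained_parameters(neat_records_small,
                                                     neat_truth):
    """Freeing a pair that never occurs in the data must fail loudly."""
    params = neat_truth.copy()
    params.pairs[("ZZ", "ZZ")] = PairParams(A=1.0, b=3.0)
    stage = FitStage("bad", [("A", ("ZZ", "ZZ"))],
                     w_atomic=1.0, w_molforce=0.0, w_torque=0.0)
    with pytest.raises(SingularFitError, match="ZZ"):
        fit_stage(params, neat_records_small, stage)


def test_more_parameters_than_residuals_rejected(neat_truth):
    records, _ = gen_training_set(seed=1, phase="neat", n_configs=1,
                                  n_molecules=1)
    keys = [(kind, k) for k in sorted(neat_truth.pairs)
            for kind in ("A", "b")]
    stage = FitStage("inter", keys, w_atomic=0.0, w_molforce=1.0, w_torque=1.0)
    with pytest.raises(ValueError, match="residual components"):
        fit_stage(neat_truth, records, stage)


# ---------------------------------------------------------------------------
# Mixed-phase joint fit
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mixed_phase_fits(hydrated_truth, hydrated_records_small):
    neat_records, _ = gen_training_set(seed=11, phase="neat", n_configs=6,
                                       n_molecules=4, scheme=HYDRATED_SCHEME,
                                       params=hydrated_truth)
    rng = np.random.default_rng(6)
    cross = [k for k in hydrated_truth.pairs
             if (set(k) & HYDRATED_TYPES) and (set(k) & SOLVENT_TYPES)]
    keys = [(kind, k) for k in cross for kind in ("A", "b")] \
        + [("q", t) for t in sorted(HYDRATED_TYPES)]
    start = perturbed_params(hydrated_truth, keys, rng, 0.1)
    hyd_fit = fit_hydrated(start, hydrated_records_small, HYDRATED_TYPES)
    joint = joint_mixed_phase_fit(neat_records, hydrated_records_small,
                                  start, HYDRATED_TYPES)
    return {"truth": hydrated_truth, "cross": cross, "start": start,
            "hydrated_only": hyd_fit, "joint": joint,
            "neat_records": neat_records}


def test_joint_fit_leaves_solute_solvent_parameters_identical(mixed_phase_fits):
    """Neat records carry no solute-solvent pairs, so the joint fit cannot
    move those parameters (asserted exactly)."""
    ph, pm = mixed_phase_fits["hydrated_only"], mixed_phase_fits["joint"]
    for k in mixed_phase_fits["cross"]:
        assert abs(pm.pairs[k].A - ph.pairs[k].A) <= 1e-10
        assert abs(pm.pairs[k].b - ph.pairs[k].b) <= 1e-10
    for t in HYDRATED_TYPES:
        assert pm.charges[t] == ph.charges[t]


def test_joint_fit_recovers_common_ground_truth(mixed_phase_fits):
    truth, joint = mixed_phase_fits["truth"], mixed_phase_fits["joint"]
    for k, p in truth.pairs.items():
        if set(k) <= HYDRATED_TYPES or (set(k) & SOLVENT_TYPES and set(k) & HYDRATED_TYPES):
            assert joint.pairs[k].A == pytest.approx(p.A, rel=1e-3)
            assert joint.pairs[k].b == pytest.approx(p.b, rel=1e-3)
    for t in HYDRATED_TYPES:
        assert joint.charges[t] == pytest.approx(truth.charges[t], rel=1e-3)


def test_joint_fit_without_neat_records_equals_hydrated_fit(
        mixed_phase_fits, hydrated_records_small):
    joint_empty = joint_mixed_phase_fit([], hydrated_records_small,
                                        mixed_phase_fits["start"],
                                        HYDRATED_TYPES)
    ph = mixed_phase_fits["hydrated_only"]
    for k in mixed_phase_fits["cross"]:
        assert joint_empty.pairs[k].A == pytest.approx(ph.pairs[k].A, abs=1e-12)
        assert joint_empty.pairs[k].b == pytest.approx(ph.pairs[k].b, abs=1e-12)


def test_joint_fit_requires_phase_data(hydrated_truth):
    with pytest.raises(ValueError):
        joint_mixed_phase_fit([], [], hydrated_truth, HYDRATED_TYPES)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_metrics_of_perfect_agreement():
    x = np.array([1.0, -2.0, 3.0, 0.5])
    m = regression_metrics(x, x)
    assert m.rmse == 0.0
    assert m.slope == pytest.approx(1.0)
    assert m.r2 == pytest.approx(1.0)


def test_metrics_constant_offset_rmse():
    ref = np.array([0.0, 1.0, -1.0, 2.0])
    m = regression_metrics(ref + 3.0, ref)
    assert m.rmse == pytest.approx(3.0)


def test_metrics_scaled_model_against_hand_least_squares():
    ref = np.array([1.0, 2.0, 3.0])
    m = regression_metrics(2.0 * ref, ref)
    # through-origin slope: sum(x*y)/sum(x^2) = 28/14
    assert m.slope == pytest.approx(2.0)
    assert m.rmse == pytest.approx(np.sqrt(14.0 / 3.0))


def test_metrics_require_two_points():
    with pytest.raises(ValueError):
        regression_metrics(np.array([1.0]), np.array([1.0]))
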