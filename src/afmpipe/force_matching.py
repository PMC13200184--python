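"""Staged weighted least-squares force matching.

Force-field parameters are fitted to reference per-atom forces by minimizing
the weighted squared difference between model and reference over three
observable classes: masked atomic forces, molecular net forces and molecular
torques about the center of mass.  Molecular net forces/torques are blind to
intramolecular terms (internal forces cancel exactly), so the conventional
staging — intermolecular parameters first, from molecular observables, then
intramolecular parameters from atomic forces — decouples the two blocks.

Parameters that enter the forces linearly (repulsion prefactors A, dispersion
C6/C8, bond/angle stiffnesses, dihedral cosine coefficients) are solved by
exact linear least squares; the remaining parameters (Buckingham decays b,
equilibrium geometry r0/theta0, partial charges — quadratic through q_i*q_j
products) are refined by bounded nonlinear search with the linear solve
nested inside (variable projection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model_core import (
    Configuration,
    ForceFieldParams,
    ForceRecord,
    InteractionTerms,
    evaluate_terms,
    precompute_terms,
)

LINEAR_KINDS = {"A", "C6", "C8", "bond_k", "angle_k", "dih_c"}
NONLINEAR_KINDS = {"b", "q", "bond_r0", "angle_theta0"}

DEFAULT_BOUNDS = {
    "b": (1.0, 10.0),
    "q": (-3.0, 3.0),
    "bond_r0": (0.6, 2.5),
    "angle_theta0": (0.5, 3.1),
}


class SingularFitError(ValueError):
    """Design matrix rank-deficient; names the unconstrained parameters."""


# ---------------------------------------------------------------------------
# Parameter addressing
# ---------------------------------------------------------------------------

def get_param(params: ForceFieldParams, key: tuple) -> float:
    kind = key[0]
    if kind == "A":
        return params.pair(*key[1]).A
    if kind == "b":
        return params.pair(*key[1]).b
    if kind == "C6":
        return params.pair(*key[1]).C6
    if kind == "C8":
        return params.pair(*key[1]).C8
    if kind == "q":
        return params.charges.get(key[1], 0.0)
    if kind == "bond_r0":
        return params.bonds[key[1]][0]
    if kind == "bond_k":
        return params.bonds[key[1]][1]
    if kind == "angle_theta0":
        return params.angles[key[1]][0]
    if kind == "angle_k":
        return params.angles[key[1]][1]
    if kind == "dih_c":
        return params.dihedrals[key[1]][key[2]]
    raise KeyError(f"unknown parameter kind {kind!r}")


def set_param(params: ForceFieldParams, key: tuple, value: float) -> None:
    kind = key[0]
    if kind in ("A", "b", "C6", "C8"):
        setattr(params.pair(*key[1]), kind, float(value))
    elif kind == "q":
        params.charges[key[1]] = float(value)
    elif kind == "bond_r0":
        r0, k = params.bonds[key[1]]
        params.bonds[key[1]] = (float(value), k)
    elif kind == "bond_k":
        r0, k = params.bonds[key[1]]
        params.bonds[key[1]] = (r0, float(value))
    elif kind == "angle_theta0":
        t0, k = params.angles[key[1]]
        params.angles[key[1]] = (float(value), k)
    elif kind == "angle_k":
        t0, k = params.angles[key[1]]
        params.angles[key[1]] = (t0, float(value))
    elif kind == "dih_c":
        c = list(params.dihedrals[key[1]])
        c[key[2]] = float(value)
        params.dihedrals[key[1]] = tuple(c)
    else:
        raise KeyError(f"unknown parameter kind {kind!r}")


# ---------------------------------------------------------------------------
# Training data
# ---------------------------------------------------------------------------

@dataclass
class TrainingRecord:
    """A configuration paired with reference forces.

    ``mask`` selects the atoms whose forces enter the objective (all atoms for
    neat records; solute atoms for QM/MM-style hydrated records).  Molecular
    observables are taken over molecules fully covered by the mask.
    """

    configuration: Configuration
    reference_forces: np.ndarray      # (N, 3) kcal/(mol*A)
    phase: str = "neat"
    mask: np.ndarray | None = None    # bool (N,) — default: all atoms

    def __post_init__(self) -> None:
        self.reference_forces = np.asarray(self.reference_forces, dtype=float)
        if self.reference_forces.shape != (self.configuration.n_atoms, 3):
            raise ValueError("reference forces shape mismatch")
        if not np.all(np.isfinite(self.reference_forces)):
            raise ValueError("non-finite reference forces")
        if self.mask is None:
            self.mask = np.ones(self.configuration.n_atoms, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty active-atom mask")
        if self.phase not in ("neat", "hydrated"):
            raise ValueError(f"unknown phase tag {self.phase!r}")


@dataclass
class FitStage:
    """One fitting stage: which parameters float and with what weights.

    Torque residuals are divided by ``torque_lever`` (Angstrom) so all three
    observable classes share force units.
    """

    name: str
    free: list[tuple]
    w_atomic: float = 1.0
    w_molforce: float = 1.0
    w_torque: float = 1.0
    ridge: float = 0.0
    torque_lever: float = 1.0
    bounds: dict = field(default_factory=dict)

    def split_free(self) -> tuple[list[tuple], list[tuple]]:
        lin = [k for k in self.free if k[0] in LINEAR_KINDS]
        nonlin = [k for k in self.free if k[0] in NONLINEAR_KINDS]
        unknown = [k for k in self.free if k[0] not in LINEAR_KINDS | NONLINEAR_KINDS]
        if unknown:
            raise KeyError(f"unknown parameter kinds in stage: {unknown}")
        return lin, nonlin


def validate_stage_spec(stages: list[FitStage], params: ForceFieldParams) -> None:
    """Dispersion stays frozen in every stage; intermolecular precedes
    intramolecular."""
    intra_seen = False
    for st in stages:
        for key in st.free:
            if params.dispersion_frozen and key[0] in ("C6", "C8"):
                raise ValueError(
                    f"stage {st.name!r} frees dispersion {key} but dispersion is frozen"
                )
            if key[0] in ("bond_k", "bond_r0", "angle_k", "angle_theta0", "dih_c"):
                intra_seen = True
            elif key[0] in ("A", "b", "q") and intra_seen:
                raise ValueError(
                    "intermolecular parameters must be fitted before intramolecular ones"
                )


# ---------------------------------------------------------------------------
# Observable projection
# ---------------------------------------------------------------------------

class _Projector:
    """Maps an (N,3) force array to (atomic, molforce, torque) blocks."""

    def __init__(self, record: TrainingRecord):
        cfg = record.configuration
        self.mask_idx = np.nonzero(record.mask)[0]
        masses = cfg.masses()
        self.mol_atoms: list[np.ndarray] = []
        self.lever: list[np.ndarray] = []
        for idx in cfg.molecules:
            if not record.mask[idx].all():
                continue
            m = masses[idx]
            com = np.sum(m[:, None] * cfg.coords[idx], axis=0) / np.sum(m)
            self.mol_atoms.append(idx)
            self.lever.append(cfg.coords[idx] - com)

    def project(self, forces: np.ndarray):
        atomic = forces[self.mask_idx].ravel()
        molf = np.array([np.sum(forces[idx], axis=0) for idx in self.mol_atoms])
        torque = np.array([
            np.sum(np.cross(lev, forces[idx]), axis=0)
            for idx, lev in zip(self.mol_atoms, self.lever)
        ])
        return atomic, molf.ravel(), torque.ravel()


@dataclass
class _Workspace:
    terms: list[InteractionTerms]
    projectors: list[_Projector]
    ref_blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]]


def _build_workspace(records: list[TrainingRecord], cutoff: float) -> _Workspace:
    if not records:
        raise ValueError("empty training set")
    terms, projs, refs = [], [], []
    for rec in records:
        terms.append(precompute_terms(rec.configuration, cutoff))
        p = _Projector(rec)
        projs.append(p)
        refs.append(p.project(rec.reference_forces))
    return _Workspace(terms, projs, refs)


def _stack_obs(stage: FitStage, blocks) -> np.ndarray:
    """Concatenate weighted observable blocks (zero-weight blocks dropped)."""
    out = []
    for (atomic, molf, torque) in blocks:
        if stage.w_atomic > 0:
            out.append(np.sqrt(stage.w_atomic) * atomic)
        if stage.w_molforce > 0:
            out.append(np.sqrt(stage.w_molforce) * molf)
        if stage.w_torque > 0:
            out.append(np.sqrt(stage.w_torque) * torque / stage.torque_lever)
    return np.concatenate(out) if out else np.zeros(0)


# ---------------------------------------------------------------------------
# Residuals
# ---------------------------------------------------------------------------

def fm_residuals(params: ForceFieldParams, records: list[TrainingRecord],
                 stage: FitStage, cutoff: float = 12.0) -> np.ndarray:
    """Weighted residual vector sqrt(w)*(model - reference)."""
    ws = _build_workspace(records, cutoff)
    model_blocks = []
    for t, p in zip(ws.terms, ws.projectors):
        _, rec = evaluate_terms(t, params)
        model_blocks.append(p.project(rec.forces))
    return _stack_obs(stage, model_blocks) - _stack_obs(stage, ws.ref_blocks)


# ---------------------------------------------------------------------------
# Basis (design) columns for linear parameters
# ---------------------------------------------------------------------------

def _linear_basis_forces(key: tuple, terms: InteractionTerms,
                         params: ForceFieldParams) -> np.ndarray:
    """d(forces)/d(linear parameter) for one configuration."""
    n = terms.config.n_atoms
    F = np.zeros((n, 3))
    kind = key[0]
    if kind in ("A", "C6", "C8"):
        if key[1] not in terms.pair_keys:
            return F
        idx = terms.pair_keys.index(key[1])
        sel = terms.pair_key_idx == idx
        if not sel.any():
            return F
        r = terms.pair_r[sel]
        if kind == "A":
            b = params.pair(*key[1]).b
            du = -b * np.exp(-b * r)
        elif kind == "C6":
            du = 6.0 / r**7
        else:
            du = 8.0 / r**9
        scale = np.where(np.isnan(terms.pair_scale[sel]), params.scale_14,
                         terms.pair_scale[sel])
        fvec = -((scale * du) / r)[:, None] * terms.pair_dr[sel]
        np.add.at(F, terms.pair_i[sel], fvec)
        np.add.at(F, terms.pair_j[sel], -fvec)
    elif kind == "bond_k":
        if key[1] not in terms.bond_keys:
            return F
        idx = terms.bond_keys.index(key[1])
        sel = terms.bond_key_idx == idx
        r0 = params.bonds[key[1]][0]
        dr_ = terms.bond_r[sel] - r0
        f = -dr_[:, None] * terms.bond_unit[sel]
        np.add.at(F, terms.bond_ij[sel, 0], f)
        np.add.at(F, terms.bond_ij[sel, 1], -f)
    elif kind == "angle_k":
        if key[1] not in terms.angle_keys:
            return F
        idx = terms.angle_keys.index(key[1])
        sel = terms.angle_key_idx == idx
        t0 = params.angles[key[1]][0]
        coef = -(terms.angle_theta[sel] - t0)
        for a in range(3):
            np.add.at(F, terms.angle_ijk[sel, a],
                      coef[:, None] * terms.angle_grads[sel, a, :])
    elif kind == "dih_c":
        if key[1] not in terms.dihedral_keys:
            return F
        idx = terms.dihedral_keys.index(key[1])
        sel = terms.dihedral_key_idx == idx
        nharm = key[2]
        # E = cos(n phi) -> force = +n sin(n phi) * dphi/dr
        coef = nharm * np.sin(nharm * terms.dihedral_phi[sel])
        for a in range(4):
            np.add.at(F, terms.dihedral_ijkl[sel, a],
                      coef[:, None] * terms.dihedral_grads[sel, a, :])
    else:
        raise KeyError(f"{kind!r} is not a linear parameter kind")
    return F


def _design_and_target(params: ForceFieldParams, lin_keys: list[tuple],
                       ws: _Workspace, stage: FitStage
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix over linear parameters and the residual target vector."""
    base = params.copy()
    for key in lin_keys:
        set_param(base, key, 0.0)
    cols = [[] for _ in lin_keys]
    f0_blocks = []
    for t, proj in zip(ws.terms, ws.projectors):
        _, rec = evaluate_terms(t, base)
        f0_blocks.append(proj.project(rec.forces))
        for c, key in enumerate(lin_keys):
            cols[c].append(proj.project(_linear_basis_forces(key, t, params)))
    y = _stack_obs(stage, ws.ref_blocks) - _stack_obs(stage, f0_blocks)
    design = np.column_stack([_stack_obs(stage, col) for col in cols]) \
        if lin_keys else np.zeros((len(y), 0))
    return design, y


def _solve_linear(design: np.ndarray, y: np.ndarray, lin_keys: list[tuple],
                  ridge: float) -> np.ndarray:
    if design.shape[1] == 0:
        return np.zeros(0)
    norms = np.linalg.norm(design, axis=0)
    scale = max(np.max(norms), 1.0)
    dead = norms < 1e-12 * scale
    if dead.any():
        names = [lin_keys[i] for i in np.nonzero(dead)[0]]
        raise SingularFitError(f"unconstrained parameters (zero design columns): {names}")
    lam = ridge
    if lam == 0.0:
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            lam = 1e-8
            warnings.warn(
                "rank-deficient force-matching design; enabling ridge 1e-8",
                RuntimeWarning,
            )
    if lam > 0.0:
        aug = np.vstack([design, np.sqrt(lam) * np.eye(design.shape[1])])
        yaug = np.concatenate([y, np.zeros(design.shape[1])])
        theta, *_ = np.linalg.lstsq(aug, yaug, rcond=None)
    else:
        theta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return theta


# ---------------------------------------------------------------------------
# Stage fitting (variable projection)
# ---------------------------------------------------------------------------

def fit_stage(params: ForceFieldParams, records: list[TrainingRecord],
              stage: FitStage, cutoff: float = 12.0) -> ForceFieldParams:
    """Minimize the stage's weighted objective over its free parameters.

    Returns updated parameters; frozen parameters are untouched.
    """
    ws = _build_workspace(records, cutoff)
    lin_keys, nl_keys = stage.split_free()
    n_obs = len(_stack_obs(stage, ws.ref_blocks))
    if n_obs < len(stage.free):
        raise ValueError(
            f"{n_obs} residual components for {len(stage.free)} free parameters"
        )

    work = params.copy()

    def solve_at(nl_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        for key, v in zip(nl_keys, nl_values):
            set_param(work, key, v)
        design, y = _design_and_target(work, lin_keys, ws, stage)
        theta = _solve_linear(design, y, lin_keys, stage.ridge)
        resid = design @ theta - y if len(lin_keys) else -y
        return theta, resid

    if nl_keys:
        x0 = np.array([get_param(work, k) for k in nl_keys])
        lo = np.array([stage.bounds.get(k, DEFAULT_BOUNDS[k[0]])[0] for k in nl_keys])
        hi = np.array([stage.bounds.get(k, DEFAULT_BOUNDS[k[0]])[1] for k in nl_keys])
        x0 = np.clip(x0, lo, hi)
        res = least_squares(
            lambda x: solve_at(x)[1], x0, bounds=(lo, hi), method="trf",
            ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000,
        )
        theta, _ = solve_at(res.x)
        for key, v in zip(nl_keys, res.x):
            set_param(work, key, v)
    else:
        theta, _ = solve_at(np.zeros(0))

    for key, v in zip(lin_keys, theta):
        set_param(work, key, v)
    return work


def staged_fit(params: ForceFieldParams, records: list[TrainingRecord],
               stages: list[FitStage], cutoff: float = 12.0) -> ForceFieldParams:
    validate_stage_spec(stages, params)
    out = params
    for st in stages:
        out = fit_stage(out, records, st, cutoff=cutoff)
    return out


# ---------------------------------------------------------------------------
# Default stage construction
# ---------------------------------------------------------------------------

def present_keys(records: list[TrainingRecord], cutoff: float = 12.0):
    """Pair / bonded term keys actually present in a training set."""
    pair, bond, angle, dih = set(), set(), set(), set()
    for rec in records:
        t = precompute_terms(rec.configuration, cutoff)
        pair.update(t.pair_keys)
        bond.update(t.bond_keys)
        angle.update(t.angle_keys)
        dih.update(t.dihedral_keys)
    return pair, bond, angle, dih


def default_stages(records: list[TrainingRecord], solute_types: set[str],
                   params: ForceFieldParams, fit_charges: bool = False,
                   intermolecular_only_pairs: set | None = None,
                   dihedral_order: int = 4, cutoff: float = 12.0
                   ) -> list[FitStage]:
    """Two-stage spec: intermolecular (molecular force/torque observables)
    then intramolecular (atomic forces).

    Free nonbonded pairs: present pairs with at least one solute type, unless
    restricted to ``intermolecular_only_pairs``.  Free bonded terms: present
    term types entirely within ``solute_types``.  Dihedral cosine coefficients
    n = 1..order-1 float (the n = 0 constant exerts no force).
    """
    pair, bond, angle, dih = present_keys(records, cutoff)
    free_pairs = sorted(
        k for k in pair if (set(k) & solute_types)
        and (intermolecular_only_pairs is None or k in intermolecular_only_pairs)
    )
    inter: list[tuple] = []
    for k in free_pairs:
        inter.append(("A", k))
        inter.append(("b", k))
    if fit_charges:
        for t in sorted(solute_types):
            inter.append(("q", t))
    intra: list[tuple] = []
    for k in sorted(b for b in bond if set(b) <= solute_types):
        intra.append(("bond_k", k))
        intra.append(("bond_r0", k))
    for k in sorted(a for a in angle if set(a) <= solute_types):
        intra.append(("angle_k", k))
        intra.append(("angle_theta0", k))
    for k in sorted(d for d in dih if set(d) <= solute_types):
        order = len(params.dihedrals.get(k, (0.0,) * dihedral_order))
        for n in range(1, order):
            intra.append(("dih_c", k, n))
    return [
        FitStage("intermolecular", inter, w_atomic=0.0, w_molforce=1.0, w_torque=1.0),
        FitStage("intramolecular", intra, w_atomic=1.0, w_molforce=0.0, w_torque=0.0),
    ]


# ---------------------------------------------------------------------------
# Hydrated-only and mixed-phase joint fits
# ---------------------------------------------------------------------------

def _solvent_types(records: list[TrainingRecord], solute_types: set[str],
                   cutoff: float) -> set[str]:
    pair, *_ = present_keys(records, cutoff)
    all_types = set()
    for k in pair:
        all_types.update(k)
    return all_types - solute_types


def fit_hydrated(params: ForceFieldParams, records: list[TrainingRecord],
                 solute_types: set[str], fit_charges: bool = True,
                 cutoff: float = 12.0) -> ForceFieldParams:
    """Infinite-dilution fit: solute-solvent nonbonded (+ solute charges),
    then solute bonded terms, from QM/MM-style masked records."""
    solv = _solvent_types(records, solute_types, cutoff)
    pair, *_ = present_keys(records, cutoff)
    cross = {k for k in pair if (set(k) & solute_types) and (set(k) & solv)}
    stages = default_stages(records, solute_types, params,
                            fit_charges=fit_charges,
                            intermolecular_only_pairs=cross, cutoff=cutoff)
    return staged_fit(params, records, stages, cutoff=cutoff)


def joint_mixed_phase_fit(neat_records: list[TrainingRecord],
                          hydrated_records: list[TrainingRecord],
                          params: ForceFieldParams,
                          solute_types: set[str],
                          charge_policy: str | dict = "from_hydrated_fit",
                          cutoff: float = 12.0) -> ForceFieldParams:
    """Mixed-phase model: one parameter set describing both phases.

    Solute-solvent nonbonded parameters (and, under the default charge
    policy, the partial charges) come from the hydrated-only fit — neat
    records contain no solute-solvent pairs, so including them cannot move
    those parameters.  Solute-solute nonbonded parameters are then fitted to
    the neat records' molecular observables, and finally a single bonded
    parameter set is fitted to the masked atomic forces of both phases.
    """
    if not hydrated_records:
        raise ValueError("hydrated training set is empty")
    for rec in neat_records + hydrated_records:
        if rec.phase not in ("neat", "hydrated"):
            raise ValueError("phase tags missing")

    if isinstance(charge_policy, dict):
        work = params.copy()
        work.charges.update(charge_policy)
        work = fit_hydrated(work, hydrated_records, solute_types,
                            fit_charges=False, cutoff=cutoff)
    elif charge_policy == "from_hydrated_fit":
        work = fit_hydrated(params, hydrated_records, solute_types,
                            fit_charges=True, cutoff=cutoff)
    else:
        raise ValueError(f"unknown charge policy {charge_policy!r}")

    if neat_records:
        pair, *_ = present_keys(neat_records, cutoff)
        solute_pairs = {k for k in pair if set(k) <= solute_types}
        inter = []
        for k in sorted(solute_pairs):
            inter.append(("A", k))
            inter.append(("b", k))
        st = FitStage("neat-intermolecular", inter,
                      w_atomic=0.0, w_molforce=1.0, w_torque=1.0)
        work = fit_stage(work, neat_records, st, cutoff=cutoff)

    combined = neat_records + hydrated_records
    intra_stage = default_stages(combined, solute_types, work, cutoff=cutoff)[1]
    work = fit_stage(work, combined, intra_stage, cutoff=cutoff)
    return work


# ---------------------------------------------------------------------------
# Fit-quality metrics
# ---------------------------------------------------------------------------

@dataclass
class FitMetrics:
    """RMSE, regression slope and R^2 per observable class."""

    rmse: float
    slope: float
    r2: float


def regression_metrics(model: np.ndarray, reference: np.ndarray,
                       through_origin: bool = True) -> FitMetrics:
    """Pooled-component fit metrics of model values against reference.

    Slope and R^2 come from ordinary least squares of model on reference; the
    through-origin convention (default) reflects that forces are signed and
    symmetric about zero, and uses the uncentered total sum of squares.
    """
    model = np.asarray(model, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    if model.shape != reference.shape or len(model) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    rmse = float(np.sqrt(np.mean((model - reference) ** 2)))
    if through_origin:
        slope = float(np.dot(reference, model) / np.dot(reference, reference))
        ss_res = float(np.sum((model - slope * reference) ** 2))
        ss_tot = float(np.sum(model**2))
    else:
        slope, intercept = np.polyfit(reference, model, 1)
        pred = slope * reference + intercept
        ss_res = float(np.sum((model - pred) ** 2))
        ss_tot = float(np.sum((model - np.mean(model)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitMetrics(rmse=rmse, slope=float(slope), r2=float(r2))


def compute_fit_metrics(params: ForceFieldParams, records: list[TrainingRecord],
                        cutoff: float = 12.0, through_origin: bool = True
                        ) -> dict[str, FitMetrics]:
    """Model-vs-reference metrics for molecular force, molecular torque and
    atomic force, pooled over vector components of the whole training set."""
    ws = _build_workspace(records, cutoff)
    m_at, m_mf, m_tq = [], [], []
    r_at, r_mf, r_tq = [], [], []
    for t, proj, ref in zip(ws.terms, ws.projectors, ws.ref_blocks):
        _, rec = evaluate_terms(t, params)
        a, f, q = proj.project(rec.forces)
        m_at.append(a); m_mf.append(f); m_tq.append(q)
        r_at.append(ref[0]); r_mf.append(ref[1]); r_tq.append(ref[2])
    cat = np.concatenate
    return {
        "molecular_force": regression_metrics(cat(m_mf), cat(r_mf), through_origin),
        "molecular_torque": regression_metrics(cat(m_tq), cat(r_tq), through_origin),
        "atomic_force": regression_metrics(cat(m_at), cat(r_at), through_origin),
    }
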