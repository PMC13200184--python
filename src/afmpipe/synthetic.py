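"""Seeded synthetic-data generators with known ground truth.

These generators stand in for the electronic-structure and molecular-dynamics
stages of the workflow: reference forces come from a known ground-truth force
field (plus optional Gaussian noise), and trajectory-derived observables are
drawn from stochastic models whose parameters (surface tension, critical
point, Antoine coefficients, diffusion constant, compressibility) are the
recovery targets.  Every generator returns its output together with a
manifest recording the seed and ground truth, and identical inputs produce
bit-identical outputs.

Default observable truths are set to a cyclohexene-like liquid: surface
tension 25.4 mN/m (slab L_Z = 12 nm), diffusion constant 0.99e-5 cm^2/s,
isothermal compressibility 1.0366e-3 MPa^-1, coexistence temperatures
360-460 K, and free-energy sampling temperatures 298.15/344/364 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AMU_PER_A3_TO_G_PER_L, ATOMIC_MASSES, KB_J_PER_K
from .force_matching import TrainingRecord
from .model_core import (
    Configuration,
    ForceFieldParams,
    MolecularGraph,
    PairParams,
    assign_atom_types,
    AtomTypeScheme,
    bond_key,
    evaluate_energy_forces,
    HYDRATED_SCHEME,
    NEAT_SCHEME,
)
from .slab import DensityProfile, PressureTensorSeries
from .thermo import AntoineFit, CoexistenceCurve, VaporPressureCurve

# fixed substream ids so each scenario is independently reproducible
_STREAMS = {
    "training_neat": 1,
    "training_hydrated": 2,
    "pressure": 3,
    "slab": 4,
    "coexistence": 5,
    "vapor_pressure": 6,
    "brownian": 7,
    "volume": 8,
    "stress": 9,
    "brownian_pure": 10,
    "training_neat_noise": 11,
    "training_hydrated_noise": 12,
}

# observable ground-truth defaults (cyclohexene-like liquid)
DEFAULT_GAMMA_MN_M = 25.4
DEFAULT_LZ_NM = 12.0
DEFAULT_D_CM2_S = 0.99e-5
DEFAULT_KAPPA_T_MPA = 1.0366e-3
DEFAULT_TC_K = 513.0
DEFAULT_RHOC_G_L = 303.9
# Wegner difference amplitudes (g/L)
DEFAULT_WEGNER_AMPLITUDES = (579.5, 4637.6, -8973.0, 5706.9)
# rectilinear-diameter coefficients chosen so vapor densities stay positive
# and of ideal-gas magnitude over the sampled window
DEFAULT_D_1MA = -350.0
DEFAULT_D_1 = 1496.8
DEFAULT_COEX_TEMPS = (360.0, 380.0, 400.0, 420.0, 440.0, 460.0)
# Antoine truth: boiling point 344 K at 1 atm with a Clausius-Clapeyron slope
# matching a vaporization enthalpy of ~33.5 kJ/mol
DEFAULT_ANTOINE = AntoineFit(A=10.352, B=-3143.0, C=-40.0,
                             T_min=290.0, T_max=470.0, pressure_unit="bar")
DEFAULT_FREE_ENERGY_TEMPS = (298.15, 344.0, 364.0)


def stream_rng(seed: int, scenario: str) -> np.random.Generator:
    """Deterministic per-scenario random stream fanned out from one seed."""
    if scenario not in _STREAMS:
        raise KeyError(f"unknown scenario {scenario!r}")
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), _STREAMS[scenario]))
    )


@dataclass
class SyntheticSpec:
    """Scenario description: seed, ground truth and sizes.

    ``ground_truth`` and ``sizes`` are echoed into every manifest.
    """

    seed: int
    scenario: str
    ground_truth: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    sizes: dict = field(default_factory=dict)


def _manifest(spec_like: dict) -> dict:
    return dict(spec_like)


# ---------------------------------------------------------------------------
# Ground-truth force field
# ---------------------------------------------------------------------------

_BASE_NONBONDED = {
    # per-type base (A kcal/mol, b 1/A, C6 kcal A^6/mol)
    "CD": (33000.0, 3.55, 560.0),
    "CS": (31000.0, 3.60, 540.0),
    "CA": (31500.0, 3.58, 545.0),
    "CB": (30500.0, 3.62, 535.0),
    "HD": (2900.0, 3.72, 28.0),
    "HS": (2700.0, 3.76, 26.0),
    "HA": (2750.0, 3.74, 27.0),
    "HB": (2650.0, 3.78, 25.0),
    "OW": (42000.0, 3.85, 430.0),
    "HW": (1300.0, 4.00, 10.0),
}

_HYDRATED_CHARGES = {
    "CD": -0.12, "CA": -0.06, "CB": -0.10,
    "HD": 0.10, "HA": 0.05, "HB": 0.04,
    "OW": -0.80, "HW": 0.40,
}

SOLVENT_TYPES = {"OW", "HW"}


def _pair_table(types: list[str], rng: np.random.Generator
                ) -> dict[tuple[str, str], PairParams]:
    """Pair-specific table: geometric/arithmetic base values perturbed by up
    to 8% per pair, so no combining rule can reconstruct the truth."""
    table = {}
    for i, a in enumerate(types):
        for b in types[i:]:
            pa, pb = _BASE_NONBONDED[a], _BASE_NONBONDED[b]
            da, db, dc = rng.uniform(-0.08, 0.08, 3)
            table[bond_key(a, b)] = PairParams(
                A=float(np.sqrt(pa[0] * pb[0]) * (1 + da)),
                b=float(0.5 * (pa[1] + pb[1]) * (1 + 0.25 * db)),
                C6=float(np.sqrt(pa[2] * pb[2]) * (1 + dc)),
            )
    return table


def cyclohexene_template() -> np.ndarray:
    """Approximate puckered-ring cyclohexene-like geometry (Angstrom),
    atom order matching :meth:`MolecularGraph.cyclohexene`."""
    r_ring = 1.45
    pucker = np.array([0.0, 0.0, 0.28, -0.28, 0.28, -0.28])
    ring = np.array([
        [r_ring * np.cos(np.pi / 3 * c), r_ring * np.sin(np.pi / 3 * c), pucker[c]]
        for c in range(6)
    ])
    graph = MolecularGraph.cyclohexene()
    nb = graph.neighbors()
    coords = [ring[c] for c in range(6)]
    for c in range(6):
        ring_nb = [j for j in nb[c] if j < 6]
        u1 = ring[ring_nb[0]] - ring[c]
        u2 = ring[ring_nb[1]] - ring[c]
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bis = -(u1 + u2)
        bis /= np.linalg.norm(bis)
        if c in (0, 1):          # sp2: one in-plane hydrogen
            coords.append(ring[c] + 1.09 * bis)
        else:                    # sp3: two out-of-plane hydrogens
            nrm = np.cross(u1, u2)
            nrm /= np.linalg.norm(nrm)
            ca, sa = np.cos(np.deg2rad(54.0)), np.sin(np.deg2rad(54.0))
            coords.append(ring[c] + 1.09 * (ca * bis + sa * nrm))
            coords.append(ring[c] + 1.09 * (ca * bis - sa * nrm))
    # reorder hydrogens to the graph's per-carbon order
    order = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
    return np.array(coords)[order]


def solvent_template() -> tuple[np.ndarray, list[str], list[tuple[int, int]], list[str]]:
    """Rigid 3-site bent solvent surrogate: coordinates, elements, bonds,
    type labels."""
    r_oh = 0.97
    half = np.deg2rad(104.5 / 2)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [r_oh * np.sin(half), r_oh * np.cos(half), 0.0],
        [-r_oh * np.sin(half), r_oh * np.cos(half), 0.0],
    ])
    return coords, ["O", "H", "H"], [(0, 1), (0, 2)], ["OW", "HW", "HW"]


def _measure_bonded(graph: MolecularGraph, labels: list[str],
                    coords: np.ndarray):
    """Per-type mean bond lengths and angles of a template geometry."""
    from .model_core import angle_key, bond_key as bk, dihedral_key

    bonds: dict = {}
    for i, j in graph.bonds:
        key = bk(labels[i], labels[j])
        bonds.setdefault(key, []).append(np.linalg.norm(coords[i] - coords[j]))
    angles: dict = {}
    for i, j, k in graph.angles():
        key = angle_key(labels[i], labels[j], labels[k])
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        cos_t = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        angles.setdefault(key, []).append(np.arccos(np.clip(cos_t, -1, 1)))
    dihedral_keys = sorted({
        dihedral_key(*(labels[x] for x in q)) for q in graph.dihedrals()
    })
    return ({k: float(np.mean(v)) for k, v in bonds.items()},
            {k: float(np.mean(v)) for k, v in angles.items()},
            dihedral_keys)


def ground_truth_params(scheme: AtomTypeScheme = NEAT_SCHEME,
                        include_solvent: bool = False,
                        dihedral_order: int = 4) -> ForceFieldParams:
    """The generator's ground-truth force field for the chosen typing scheme.

    Fixed (seed-independent): the same truth underlies every training set.
    """
    graph = MolecularGraph.cyclohexene()
    labels = assign_atom_types(graph, scheme)
    types = sorted(set(labels))
    if include_solvent:
        types = sorted(set(types) | SOLVENT_TYPES)
    rng = np.random.default_rng(20260920)  # fixed: the truth is one model
    params = ForceFieldParams(
        pairs=_pair_table(types, rng),
        charges_enabled=scheme.name == "hydrated",
        dispersion_frozen=True,
    )
    if params.charges_enabled:
        params.charges = {t: _HYDRATED_CHARGES[t] for t in types}

    template = cyclohexene_template()
    b_len, a_ang, d_keys = _measure_bonded(graph, labels, template)
    bond_k = {"C": 620.0, "H": 680.0}
    for key, r0 in b_len.items():
        stiff = 1050.0 if key == ("CD", "CD") else \
            (660.0 if all(t.startswith("C") for t in key) else 700.0)
        params.bonds[key] = (r0, stiff)
    for key, t0 in a_ang.items():
        stiff = 112.0 if all(t.startswith("C") for t in key) else 76.0
        params.angles[key] = (t0, stiff)
    for key in d_keys:
        c = rng.uniform(0.3, 1.5, dihedral_order)
        c[0] = 0.0  # the constant term exerts no force
        params.dihedrals[key] = tuple(float(x) for x in c)

    if include_solvent:
        from .model_core import angle_key as ak
        params.bonds[bond_key("HW", "OW")] = (0.97, 1100.0)
        params.angles[ak("HW", "OW", "HW")] = (np.deg2rad(104.5), 140.0)
    return params


# ---------------------------------------------------------------------------
# Training-set generation
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _pack_molecules(templates: list[np.ndarray], rng: np.random.Generator,
                    region: float, min_dist: float = 2.1,
                    max_attempts: int = 2000) -> list[np.ndarray]:
    """Overlap-rejected random placement of rigid copies in a cubic region."""
    placed: list[np.ndarray] = []
    for tmpl in templates:
        centered = tmpl - tmpl.mean(axis=0)
        for attempt in range(max_attempts):
            rot = _random_rotation(rng)
            pos = centered @ rot.T + rng.uniform(0, region, 3)
            ok = True
            for other in placed:
                d = np.linalg.norm(pos[:, None, :] - other[None, :, :], axis=-1)
                if d.min() < min_dist:
                    ok = False
                    break
            if ok:
                placed.append(pos)
                break
        else:
            raise RuntimeError(
                f"packing failed after {max_attempts} attempts at region "
                f"{region:.1f} A"
            )
    return placed


def _neat_configuration(n_molecules: int, rng: np.random.Generator,
                        jitter: float,
                        scheme: AtomTypeScheme = NEAT_SCHEME) -> Configuration:
    graph = MolecularGraph.cyclohexene()
    labels = assign_atom_types(graph, scheme)
    tmpl = cyclohexene_template()
    region = 6.5 * max(1.0, n_molecules ** (1 / 3))
    placed = _pack_molecules([tmpl] * n_molecules, rng, region, min_dist=2.3)
    coords, elements, mol_id, types, bonds = [], [], [], [], []
    for m, pos in enumerate(placed):
        offset = len(elements)
        coords.append(pos + rng.normal(0.0, jitter, pos.shape))
        elements.extend(graph.elements)
        mol_id.extend([m] * graph.n_atoms)
        types.extend(labels)
        bonds.extend([(i + offset, j + offset) for i, j in graph.bonds])
    return Configuration(
        coords=np.vstack(coords), elements=elements,
        molecule_id=np.array(mol_id), type_labels=types, bonds=bonds,
    )


def _hydrated_configuration(n_solvent: int, rng: np.random.Generator,
                            jitter: float, scheme: AtomTypeScheme
                            ) -> tuple[Configuration, np.ndarray]:
    """One solute centered among solvent molecules; returns (config, mask)."""
    graph = MolecularGraph.cyclohexene()
    labels = assign_atom_types(graph, scheme)
    tmpl = cyclohexene_template()
    scoords, sel_elements, sbonds, slabels = solvent_template()
    region = 6.0 * max(1.0, (n_solvent + 4) ** (1 / 3))
    placed = _pack_molecules([tmpl] + [scoords] * n_solvent, rng, region,
                             min_dist=2.0)
    coords, elements, mol_id, types, bonds = [], [], [], [], []
    specs = [(graph.elements, labels, graph.bonds)] + \
        [(sel_elements, slabels, sbonds)] * n_solvent
    for m, (pos, (els, labs, bnds)) in enumerate(zip(placed, specs)):
        offset = len(elements)
        coords.append(pos + rng.normal(0.0, jitter, pos.shape))
        elements.extend(els)
        mol_id.extend([m] * len(els))
        types.extend(labs)
        bonds.extend([(i + offset, j + offset) for i, j in bnds])
    cfg = Configuration(
        coords=np.vstack(coords), elements=elements,
        molecule_id=np.array(mol_id), type_labels=types, bonds=bonds,
    )
    mask = np.zeros(cfg.n_atoms, dtype=bool)
    mask[: graph.n_atoms] = True
    return cfg, mask


def gen_training_set(seed: int, phase: str = "neat", n_configs: int = 20,
                     n_molecules: int = 8, n_solvent: int = 22,
                     noise_sigma: float = 0.0, jitter: float = 0.05,
                     cutoff: float = 12.0,
                     params: ForceFieldParams | None = None,
                     scheme: AtomTypeScheme | None = None
                     ) -> tuple[list[TrainingRecord], dict]:
    """Training records with forces from the ground-truth force field.

    ``phase='neat'``: clusters of cyclohexene-like molecules, all atoms
    active.  ``phase='hydrated'``: one solute in a solvent-surrogate shell,
    QM/MM-style solute-only mask.  Reference forces carry i.i.d. Gaussian
    noise of standard deviation ``noise_sigma`` (kcal/(mol*A)) per component.
    """
    if phase not in ("neat", "hydrated"):
        raise ValueError(f"unknown phase {phase!r}")
    rng = stream_rng(seed, f"training_{phase}")
    rng_noise = stream_rng(seed, f"training_{phase}_noise")
    if scheme is None:
        scheme = NEAT_SCHEME if phase == "neat" else HYDRATED_SCHEME
    if params is None:
        params = ground_truth_params(scheme, include_solvent=phase == "hydrated")
    records = []
    for _ in range(n_configs):
        if phase == "neat":
            cfg = _neat_configuration(n_molecules, rng, jitter, scheme)
            mask = None
        else:
            cfg, mask = _hydrated_configuration(n_solvent, rng, jitter, scheme)
        _, rec = evaluate_energy_forces(cfg, params, cutoff)
        forces = rec.forces
        if noise_sigma > 0:
            forces = forces + rng_noise.normal(0.0, noise_sigma, forces.shape)
        records.append(TrainingRecord(
            configuration=cfg, reference_forces=forces, phase=phase, mask=mask,
        ))
    manifest = _manifest({
        "scenario": f"training_{phase}", "seed": seed,
        "n_configs": n_configs, "noise_sigma": noise_sigma,
        "cutoff_A": cutoff,
        "ground_truth": "ground_truth_params"
                        f"(scheme={scheme.name!r}, solvent={phase == 'hydrated'})",
    })
    return records, manifest


# ---------------------------------------------------------------------------
# Observable-series generators
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float
         ) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation sigma."""
    if not 0 <= rho < 1:
        raise ValueError("AR(1) correlation must be in [0, 1)")
    eps = rng.normal(0.0, sigma * np.sqrt(1 - rho**2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sigma)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + eps[t]
    return out


def gen_pressure_series(seed: int, gamma_true: float = DEFAULT_GAMMA_MN_M,
                        box_lz: float = DEFAULT_LZ_NM, mean_pz: float = 1.0,
                        sigma: float = 50.0, ar_rho: float = 0.8,
                        n: int = 5000, dt: float = 1.0
                        ) -> tuple[PressureTensorSeries, dict]:
    """Pressure-tensor series whose anisotropy encodes a target tension.

    The tangential components sit 2*gamma/L_Z (bar) below the normal one,
    so the pressure-tensor estimator recovers ``gamma_true`` (mN/m).
    """
    rng = stream_rng(seed, "pressure")
    aniso = 2.0 * (gamma_true / 0.1) / box_lz  # bar
    p_z = mean_pz + _ar1(rng, n, sigma, ar_rho)
    p_x = mean_pz - aniso + _ar1(rng, n, sigma, ar_rho)
    p_y = mean_pz - aniso + _ar1(rng, n, sigma, ar_rho)
    series = PressureTensorSeries(
        time=np.arange(n) * dt, p_x=p_x, p_y=p_y, p_z=p_z, box_lz=box_lz,
    )
    manifest = _manifest({
        "scenario": "pressure", "seed": seed, "gamma_true_mN_m": gamma_true,
        "box_lz_nm": box_lz, "anisotropy_bar": aniso, "sigma_bar": sigma,
        "ar_rho": ar_rho, "n": n,
    })
    return series, manifest


def _tanh_profile(z: np.ndarray, rho_l: float, rho_g: float, z_lo: float,
                  z_hi: float, width: float) -> np.ndarray:
    return rho_g + 0.5 * (rho_l - rho_g) * (
        np.tanh((z - z_lo) / width) - np.tanh((z - z_hi) / width)
    )


def gen_slab_profile(rho_l: float = 800.0, rho_g: float = 5.0,
                     width: float = 0.5, box_lz: float = 24.0,
                     slab_thickness: float = 8.0, n_bins: int = 100
                     ) -> tuple[DensityProfile, dict]:
    """Noiseless tanh density profile of a centered liquid slab (g/L, nm)."""
    centers = (np.arange(n_bins) + 0.5) * box_lz / n_bins
    z_lo = 0.5 * (box_lz - slab_thickness)
    z_hi = 0.5 * (box_lz + slab_thickness)
    dens = _tanh_profile(centers, rho_l, rho_g, z_lo, z_hi, width)
    profile = DensityProfile(bin_centers=centers, density=dens)
    manifest = _manifest({
        "scenario": "slab_profile", "rho_l": rho_l, "rho_g": rho_g,
        "width_nm": width, "box_lz_nm": box_lz,
        "slab_thickness_nm": slab_thickness,
    })
    return profile, manifest


def gen_slab_frames(seed: int, rho_l: float = 800.0, rho_g: float = 5.0,
                    width: float = 0.5, box_xy: float = 3.0,
                    box_lz: float = 24.0, slab_thickness: float = 8.0,
                    n_frames: int = 100,
                    cavities: list[tuple[float, float]] | None = None
                    ) -> tuple[list[Configuration], dict]:
    """Point-particle slab frames realizing a tanh density profile.

    Particles (carbon-mass markers) are placed by a Poisson process whose
    z-intensity follows the tanh profile.  ``cavities`` is a list of
    (z_center nm, radius nm) spherical voids carved out of the *same* point
    set, so cavity and cavity-free frames are paired draw by draw.
    """
    rng = stream_rng(seed, "slab")
    mass = ATOMIC_MASSES["C"]
    z_lo = 0.5 * (box_lz - slab_thickness)
    z_hi = 0.5 * (box_lz + slab_thickness)
    area_a2 = (box_xy * 10.0) ** 2
    # expected counts on a fine z-grid
    n_grid = 2000
    zg = (np.arange(n_grid) + 0.5) * box_lz / n_grid
    dens = _tanh_profile(zg, rho_l, rho_g, z_lo, z_hi, width)
    lam = dens * area_a2 * (box_lz * 10.0 / n_grid) / (AMU_PER_A3_TO_G_PER_L * mass)
    frames = []
    for _ in range(n_frames):
        counts = rng.poisson(lam)
        total = int(counts.sum())
        z = np.repeat(zg, counts) + rng.uniform(-0.5, 0.5, total) * (box_lz / n_grid)
        xy = rng.uniform(0.0, box_xy, (total, 2))
        pts = np.column_stack([xy, z])  # nm
        if cavities:
            keep = np.ones(total, dtype=bool)
            center_xy = box_xy / 2.0
            for zc, radius in cavities:
                d2 = ((pts[:, 0] - center_xy) ** 2 + (pts[:, 1] - center_xy) ** 2
                      + (pts[:, 2] - zc) ** 2)
                keep &= d2 > radius**2
            pts = pts[keep]
        frames.append(Configuration(
            coords=pts * 10.0,  # nm -> A
            elements=["C"] * len(pts),
            molecule_id=np.arange(len(pts)),
            type_labels=["X"] * len(pts),
            box=np.array([box_xy, box_xy, box_lz]) * 10.0,
            periodic=True,
        ))
    manifest = _manifest({
        "scenario": "slab", "seed": seed, "rho_l": rho_l, "rho_g": rho_g,
        "width_nm": width, "box_lz_nm": box_lz,
        "slab_thickness_nm": slab_thickness, "n_frames": n_frames,
        "cavities": cavities or [],
    })
    return frames, manifest


def wegner_difference(T: np.ndarray, T_C: float,
                      amplitudes=DEFAULT_WEGNER_AMPLITUDES) -> np.ndarray:
    from .thermo import BETA_C, DELTA
    tau = np.abs(1.0 - np.asarray(T, float) / T_C)
    exps = BETA_C + DELTA * np.arange(len(amplitudes))
    return (tau[:, None] ** exps) @ np.asarray(amplitudes)


def rectilinear_sum(T: np.ndarray, T_C: float, rho_c: float = DEFAULT_RHOC_G_L,
                    d_1ma: float = DEFAULT_D_1MA, d_1: float = DEFAULT_D_1
                    ) -> np.ndarray:
    from .thermo import ALPHA_PRIME
    tau = np.abs(1.0 - np.asarray(T, float) / T_C)
    return 2 * rho_c + d_1ma * tau ** (1 - ALPHA_PRIME) + d_1 * tau


def gen_coexistence_curve(seed: int, T_C: float = DEFAULT_TC_K,
                          amplitudes=DEFAULT_WEGNER_AMPLITUDES,
                          rho_c: float = DEFAULT_RHOC_G_L,
                          d_1ma: float = DEFAULT_D_1MA,
                          d_1: float = DEFAULT_D_1,
                          temperatures=DEFAULT_COEX_TEMPS,
                          noise_rel: float = 0.0
                          ) -> tuple[CoexistenceCurve, dict]:
    """Coexistence densities built exactly from the Wegner difference and
    rectilinear sum, then split; optional multiplicative Gaussian noise."""
    T = np.asarray(temperatures, dtype=float)
    diff = wegner_difference(T, T_C, amplitudes)
    total = rectilinear_sum(T, T_C, rho_c, d_1ma, d_1)
    rho_l = 0.5 * (total + diff)
    rho_g = 0.5 * (total - diff)
    if noise_rel > 0:
        rng = stream_rng(seed, "coexistence")
        rho_l = rho_l * (1 + rng.normal(0, noise_rel, len(T)))
        rho_g = rho_g * (1 + rng.normal(0, noise_rel, len(T)))
    curve = CoexistenceCurve(T=T, rho_l=rho_l, rho_g=rho_g)
    manifest = _manifest({
        "scenario": "coexistence", "seed": seed, "T_C": T_C,
        "amplitudes": tuple(amplitudes), "rho_c": rho_c,
        "D_1ma": d_1ma, "D_1": d_1, "noise_rel": noise_rel,
    })
    return curve, manifest


def gen_vapor_pressure_curve(seed: int, truth: AntoineFit = DEFAULT_ANTOINE,
                             temperatures=None, lognormal_sigma: float = 0.0
                             ) -> tuple[VaporPressureCurve, dict]:
    """Vapor pressures from an Antoine ground truth, with optional
    multiplicative lognormal noise."""
    from .thermo import antoine_eval
    if temperatures is None:
        temperatures = np.linspace(truth.T_min, truth.T_max, 11)
    T = np.asarray(temperatures, dtype=float)
    P = np.asarray(antoine_eval(truth, T), dtype=float)
    if lognormal_sigma > 0:
        rng = stream_rng(seed, "vapor_pressure")
        P = P * np.exp(rng.normal(0, lognormal_sigma, len(T)))
    curve = VaporPressureCurve(T=T, P=P)
    manifest = _manifest({
        "scenario": "vapor_pressure", "seed": seed,
        "antoine_truth": {"A": truth.A, "B": truth.B, "C": truth.C},
        "lognormal_sigma": lognormal_sigma,
    })
    return curve, manifest


def gen_brownian(seed: int, D_true: float = DEFAULT_D_CM2_S,
                 n_particles: int = 200, dt: float = 1.0,
                 n_steps: int = 2000,
                 stream: str = "brownian") -> tuple[np.ndarray, dict]:
    """Brownian trajectories: (n_steps+1, n_particles, 3) positions in
    Angstrom with increment variance 2*D*dt per dimension."""
    rng = stream_rng(seed, stream)
    d_a2_ps = D_true / 1e-4  # cm^2/s -> A^2/ps
    steps = rng.normal(0.0, np.sqrt(2 * d_a2_ps * dt),
                       (n_steps, n_particles, 3))
    pos = np.concatenate([
        np.zeros((1, n_particles, 3)), np.cumsum(steps, axis=0)
    ])
    manifest = _manifest({
        "scenario": "brownian", "seed": seed, "D_true_cm2_s": D_true,
        "dt_ps": dt, "n_steps": n_steps, "n_particles": n_particles,
    })
    return pos, manifest


def gen_stress_series(seed: int, eta_true: float = 0.66,
                      volume: float = 100.0, T: float = 298.15,
                      dt: float = 0.01, ar_rho: float = 0.95,
                      n: int = 100000):
    """Off-diagonal pressure series whose Green-Kubo integral matches a
    target shear viscosity (mPa*s).

    The three components are independent AR(1) processes; the marginal
    variance is calibrated so the infinite-lag trapezoidal integral of the
    exact AR(1) autocorrelation, sigma^2*dt*(1+rho)/(2(1-rho)), times
    V/(k_B T) equals ``eta_true``.
    """
    from .transport import StressSeries
    rng = stream_rng(seed, "stress")
    # target ACF integral in bar^2*ps
    integral = (eta_true * 1e-3) * KB_J_PER_K * T / (volume * 1e-27) / 1e-2
    sigma2 = integral / (dt * (1 + ar_rho) / (2 * (1 - ar_rho)))
    sigma = float(np.sqrt(sigma2))
    comps = [_ar1(rng, n, sigma, ar_rho) for _ in range(3)]
    series = StressSeries(
        time=np.arange(n) * dt, p_xy=comps[0], p_xz=comps[1], p_yz=comps[2],
        volume=volume, T=T,
    )
    manifest = _manifest({
        "scenario": "stress", "seed": seed, "eta_true_mPa_s": eta_true,
        "volume_nm3": volume, "T_K": T, "dt_ps": dt, "ar_rho": ar_rho,
        "sigma_bar": sigma, "n": n,
    })
    return series, manifest


def gen_volume_series(seed: int, kappa_t: float = DEFAULT_KAPPA_T_MPA,
                      mean_volume: float = 100.0, T: float = 298.15,
                      n: int = 100000) -> tuple[np.ndarray, dict]:
    """NPT volume series (nm^3) with fluctuations matching a target
    isothermal compressibility (MPa^-1)."""
    rng = stream_rng(seed, "volume")
    var_m6 = (kappa_t * 1e-6) * KB_J_PER_K * T * (mean_volume * 1e-27)
    sigma_nm3 = np.sqrt(var_m6) * 1e27
    series = rng.normal(mean_volume, sigma_nm3, n)
    manifest = _manifest({
        "scenario": "volume", "seed": seed, "kappa_t_MPa": kappa_t,
        "mean_volume_nm3": mean_volume, "T_K": T, "n": n,
    })
    return series, manifest
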