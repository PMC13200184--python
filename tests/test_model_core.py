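"""Graph typing, Buckingham energy/force evaluation, molecular observables
and tabulated-potential output."""

import numpy as np
import pytest

from afmpipe.model_core import (
    Configuration,
    DegenerateGeometryError,
    ForceFieldParams,
    ForceRecord,
    HYDRATED_SCHEME,
    MissingParameterError,
    MolecularGraph,
    NEAT_SCHEME,
    PairParams,
    assign_atom_types,
    enumerate_bonded_terms,
    evaluate_energy_forces,
    molecular_force_torque,
    read_tabulated_potential,
    tabulated_potential_columns,
    write_tabulated_potential,
)
from afmpipe.constants import COULOMB_KCAL_A_E2
from afmpipe.synthetic import gen_training_set

from conftest import benzene_like_graph


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scheme,n_c,n_h", [
    (NEAT_SCHEME, 2, 2),
    (HYDRATED_SCHEME, 3, 3),
])
def test_typing_distinct_label_counts(cyclohexene, scheme, n_c, n_h):
    labels = assign_atom_types(cyclohexene, scheme)
    c = {l for l, e in zip(labels, cyclohexene.elements) if e == "C"}
    h = {l for l, e in zip(labels, cyclohexene.elements) if e == "H"}
    assert len(c) == n_c
    assert len(h) == n_h


@pytest.mark.parametrize("scheme", [NEAT_SCHEME, HYDRATED_SCHEME])
def test_fully_symmetric_ring_collapses_to_one_type(scheme):
    g = benzene_like_graph()
    labels = assign_atom_types(g, scheme)
    assert len({l for l, e in zip(labels, g.elements) if e == "C"}) == 1
    assert len({l for l, e in zip(labels, g.elements) if e == "H"}) == 1


def test_typing_permutation_equivariance(cyclohexene):
    """Permuting the atoms permutes the labels identically."""
    rng = np.random.default_rng(0)
    base = assign_atom_types(cyclohexene, HYDRATED_SCHEME)
    for _ in range(5):
        perm = rng.permutation(cyclohexene.n_atoms)
        inv = np.argsort(perm)
        g2 = MolecularGraph(
            elements=[cyclohexene.elements[i] for i in perm],
            bonds=[(int(inv[i]), int(inv[j])) for i, j in cyclohexene.bonds],
            sp2_atoms=frozenset(int(inv[i]) for i in cyclohexene.sp2_atoms),
        )
        labels2 = assign_atom_types(g2, HYDRATED_SCHEME)
        assert labels2 == [base[i] for i in perm]


def test_typing_rejects_unknown_element():
    g = MolecularGraph(elements=["C", "N", "H", "H", "H", "H"],
                       bonds=[(0, 1), (0, 2), (0, 3), (0, 4), (1, 5)],
                       sp2_atoms=frozenset())
    with pytest.raises(Exception):
        assign_atom_types(g, NEAT_SCHEME)


# ---------------------------------------------------------------------------
# Bonded-term enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scheme,n_bond_types", [
    (NEAT_SCHEME, 5),
    (HYDRATED_SCHEME, 7),
])
def test_cyclohexene_bond_type_counts(cyclohexene, scheme, n_bond_types):
    labels = assign_atom_types(cyclohexene, scheme)
    terms = enumerate_bonded_terms(cyclohexene, labels)
    assert terms.n_bond_types == n_bond_types
    assert len(terms.bond_instances) == 16


def test_homonuclear_diatomic_single_bond_type():
    g = MolecularGraph(elements=["H", "H"], bonds=[(0, 1)],
                       sp2_atoms=frozenset())
    terms = enumerate_bonded_terms(g, ["A", "A"])
    assert terms.bond_types == [("A", "A")]
    assert terms.angle_types == [] and terms.dihedral_types == []


def test_missing_labels_rejected(cyclohexene):
    with pytest.raises(ValueError):
        enumerate_bonded_terms(cyclohexene, ["C"] * 4)


# ---------------------------------------------------------------------------
# Energy and forces
# ---------------------------------------------------------------------------

def _two_atom_config(r, label="X"):
    return Configuration(
        coords=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        elements=["C", "C"], molecule_id=np.array([0, 1]),
        type_labels=[label, label],
    )


def test_pure_dispersion_pair_closed_form():
    """A=0, C6=1 at r=2: E = -1/64 kcal/mol, |F| = 6/128, attractive."""
    params = ForceFieldParams(pairs={("X", "X"): PairParams(A=0.0, b=1.0, C6=1.0)},
                              charges_enabled=False)
    e, rec = evaluate_energy_forces(_two_atom_config(2.0), params, cutoff=10.0)
    assert e == pytest.approx(-1.0 / 64.0, rel=1e-12)
    assert np.linalg.norm(rec.forces[0]) == pytest.approx(6.0 / 128.0, rel=1e-12)
    # attractive: force on atom 0 points toward atom 1 (+x)
    assert rec.forces[0, 0] > 0 and rec.forces[1, 0] < 0


def test_isolated_atom_zero_energy_and_force():
    cfg = Configuration(coords=np.zeros((1, 3)), elements=["C"],
                        molecule_id=np.array([0]), type_labels=["X"])
    params = ForceFieldParams(pairs={("X", "X"): PairParams(A=1.0, b=2.0, C6=1.0)},
                              charges_enabled=False)
    e, rec = evaluate_energy_forces(cfg, params, cutoff=10.0)
    assert e == 0.0
    assert np.all(rec.forces == 0.0)


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_forces_match_finite_differences(seed, neat_truth):
    """Analytic forces equal the central-difference energy gradient."""
    recs, _ = gen_training_set(seed=seed, phase="neat", n_configs=1,
                               n_molecules=3)
    cfg = recs[0].configuration
    _, rec = evaluate_energy_forces(cfg, neat_truth, 12.0)
    h = 1e-6
    rng = np.random.default_rng(seed)
    for i in rng.choice(cfg.n_atoms, size=6, replace=False):
        for d in range(3):
            for sign, store in ((1, "p"), (-1, "m")):
                c = cfg.coords.copy()
                c[i, d] += sign * h
                e = evaluate_energy_forces(
                    Configuration(c, cfg.elements, cfg.molecule_id,
                                  cfg.type_labels, cfg.bonds), neat_truth, 12.0)[0]
                if store == "p":
                    ep = e
                else:
                    em = e
            fd = -(ep - em) / (2 * h)
            assert fd == pytest.approx(rec.forces[i, d], rel=1e-6, abs=1e-6)


def test_newtons_third_law_isolated_cluster(neat_truth):
    recs, _ = gen_training_set(seed=8, phase="neat", n_configs=1, n_molecules=5)
    _, rec = evaluate_energy_forces(recs[0].configuration, neat_truth, 12.0)
    assert np.abs(rec.forces.sum(axis=0)).max() < 1e-10


def test_overlapping_atoms_raise_degenerate_geometry():
    params = ForceFieldParams(pairs={("X", "X"): PairParams(A=1.0, b=2.0)},
                              charges_enabled=False)
    with pytest.raises(DegenerateGeometryError):
        evaluate_energy_forces(_two_atom_config(0.05), params, cutoff=10.0)


def test_missing_pair_parameters_raise():
    params = ForceFieldParams(pairs={}, charges_enabled=False)
    with pytest.raises(MissingParameterError):
        evaluate_energy_forces(_two_atom_config(2.0), params, cutoff=10.0)


def test_periodic_cutoff_exceeding_half_box_rejected():
    cfg = Configuration(
        coords=np.array([[0.0, 0, 0], [3.0, 0, 0]]), elements=["C", "C"],
        molecule_id=np.array([0, 1]), type_labels=["X", "X"],
        box=np.array([10.0, 10.0, 10.0]), periodic=True,
    )
    params = ForceFieldParams(pairs={("X", "X"): PairParams(A=1.0, b=2.0)},
                              charges_enabled=False)
    with pytest.raises(ValueError, match="half"):
        evaluate_energy_forces(cfg, params, cutoff=6.0)


def test_minimum_image_convention():
    """Atoms near opposite box faces interact across the boundary."""
    params = ForceFieldParams(pairs={("X", "X"): PairParams(A=0.0, b=1.0, C6=1.0)},
                              charges_enabled=False)
    cfg = Configuration(
        coords=np.array([[0.5, 5.0, 5.0], [9.5, 5.0, 5.0]]),
        elements=["C", "C"], molecule_id=np.array([0, 1]),
        type_labels=["X", "X"], box=np.array([10.0, 10.0, 10.0]), periodic=True,
    )
    e, _ = evaluate_energy_forces(cfg, params, cutoff=4.0)
    # image separation is 1 A, so the dispersion energy is -1/1^6
    assert e == pytest.approx(-1.0, rel=1e-12)


# ---------------------------------------------------------------------------
# Molecular net force and torque
# ---------------------------------------------------------------------------

def _simple_molecule_config():
    coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.0, 1.5, 0]])
    return Configuration(coords=coords, elements=["C", "C", "C"],
                         molecule_id=np.array([0, 0, 0]),
                         type_labels=["X"] * 3)


def test_uniform_force_gives_net_without_torque():
    cfg = _simple_molecule_config()
    f = np.array([0.3, -1.1, 0.7])
    rec = ForceRecord(forces=np.tile(f, (3, 1)))
    nets, torques = molecular_force_torque(rec, cfg)
    assert np.allclose(nets[0], 3 * f)
    assert np.allclose(torques[0], 0.0, atol=1e-12)


def test_force_couple_torque_magnitude():
    cfg = Configuration(
        coords=np.array([[0.0, 0, 0], [2.0, 0, 0]]), elements=["C", "C"],
        molecule_id=np.array([0, 0]), type_labels=["X", "X"],
    )
    f = np.array([0.0, 1.5, 0.0])
    rec = ForceRecord(forces=np.array([f, -f]))
    nets, torques = molecular_force_torque(rec, cfg)
    assert np.allclose(nets[0], 0.0)
    assert np.linalg.norm(torques[0]) == pytest.approx(2.0 * 1.5, rel=1e-12)


def test_torque_origin_independence_when_net_force_vanishes():
    """With zero net force the torque is the same about any reference point."""
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(5, 3))
    forces = rng.normal(size=(5, 3))
    forces -= forces.mean(axis=0)  # zero net force
    cfg = Configuration(coords=coords, elements=["C"] * 5,
                        molecule_id=np.zeros(5, dtype=int),
                        type_labels=["X"] * 5)
    _, torques = molecular_force_torque(ForceRecord(forces=forces), cfg)
    for _ in range(3):
        origin = rng.normal(size=3)
        brute = np.sum(np.cross(coords - origin, forces), axis=0)
        assert np.allclose(brute, torques[0], atol=1e-12)


def test_net_molecular_force_equals_sum_of_atomic_forces(neat_truth):
    recs, _ = gen_training_set(seed=6, phase="neat", n_configs=1, n_molecules=2)
    cfg = recs[0].configuration
    _, rec = evaluate_energy_forces(cfg, neat_truth, 12.0)
    nets, _ = molecular_force_torque(rec, cfg)
    for m, idx in enumerate(cfg.molecules):
        assert np.allclose(nets[m], rec.forces[idx].sum(axis=0), atol=0)


# ---------------------------------------------------------------------------
# Tabulated potentials
# ---------------------------------------------------------------------------

def test_coulomb_column_is_inverse_r():
    qq = 1.0 / COULOMB_KCAL_A_E2  # unit numerator before constant scaling
    cols = tabulated_potential_columns(PairParams(A=0.0, b=1.0),
                                       qq, np.array([1.0, 2.0, 4.0]))
    assert np.allclose(cols[:, 1], [1.0, 0.5, 0.25], rtol=1e-12)


def test_tabulated_derivative_columns_match_finite_differences(tmp_path):
    pair = PairParams(A=5000.0, b=3.5, C6=500.0, C8=20.0)
    r = np.linspace(2.0, 10.0, 8001)
    cols = tabulated_potential_columns(pair, 0.04, r)
    dr = r[1] - r[0]
    for fcol, dcol in ((1, 2), (3, 4), (5, 6)):
        fd = -(cols[2:, fcol] - cols[:-2, fcol]) / (2 * dr)
        scale = np.maximum(np.abs(cols[1:-1, dcol]), 1e-12)
        assert np.max(np.abs(fd - cols[1:-1, dcol]) / scale) < 1e-5


def test_tabulated_roundtrip_reproduces_pair_energy(tmp_path, neat_truth):
    """Sum of the re-read function columns equals the evaluator's pair
    energy on the grid."""
    key = ("CD", "CS")
    pair = neat_truth.pairs[key]
    r_grid = np.array([3.0, 4.0, 5.5, 7.0])
    path = tmp_path / "table.xvg"
    write_tabulated_potential(pair, 0.0, r_grid, path)
    table = read_tabulated_potential(path)
    params = ForceFieldParams(pairs={("X", "X"): pair}, charges_enabled=False)
    for row, r in zip(table, r_grid):
        e, _ = evaluate_energy_forces(_two_atom_config(r), params, cutoff=20.0)
        assert row[1] + row[3] + row[5] == pytest.approx(e, rel=1e-10)


def test_empty_parameters_give_zero_table():
    cols = tabulated_potential_columns(PairParams(A=0.0, b=1.0),
                                       0.0, np.array([1.0, 2.0, 3.0]))
    assert np.all(cols[:, 1:] == 0.0)


def test_non_monotone_grid_rejected():
    with pytest.raises(ValueError):
        tabulated_potential_columns(PairParams(A=1.0, b=1.0), 0.0,
                                    np.array([1.0, 3.0, 2.0]))
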