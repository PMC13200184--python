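import numpy as np
import pytest

from afmpipe.model_core import (
    HYDRATED_SCHEME,
    NEAT_SCHEME,
    MolecularGraph,
    assign_atom_types,
)
from afmpipe.synthetic import gen_training_set, ground_truth_params

NEAT_TYPES = {"CD", "CS", "HD", "HS"}
HYDRATED_TYPES = {"CD", "CA", "CB", "HD", "HA", "HB"}


@pytest.fixture(scope="session")
def cyclohexene():
    return MolecularGraph.cyclohexene()


@pytest.fixture(scope="session")
def neat_truth():
    return ground_truth_params(NEAT_SCHEME)


@pytest.fixture(scope="session")
def hydrated_truth():
    return ground_truth_params(HYDRATED_SCHEME, include_solvent=True)


@pytest.fixture(scope="session")
def neat_records_small(neat_truth):
    """Small zero-noise neat training set shared across fitting tests."""
    records, _ = gen_training_set(seed=11, phase="neat", n_configs=6,
                                  n_molecules=4)
    return records


@pytest.fixture(scope="session")
def hydrated_records_small(hydrated_truth):
    records, _ = gen_training_set(seed=11, phase="hydrated", n_configs=10,
                                  n_solvent=14)
    return records


def benzene_like_graph():
    """Fully symmetric aromatic-like ring: 6 equivalent sp2 CH units."""
    elements = ["C"] * 6 + ["H"] * 6
    bonds = [(i, (i + 1) % 6) for i in range(6)] + [(i, i + 6) for i in range(6)]
    return MolecularGraph(elements=elements, bonds=bonds)


def perturbed_params(params, keys, rng, scale):
    """Copy of params with the given parameters multiplied by 1 + U(-s, s)."""
    from afmpipe.force_matching import get_param, set_param

    out = params.copy()
    for k in keys:
        v = get_param(out, k)
        if v != 0.0:
            set_param(out, k, v * (1 + rng.uniform(-scale, scale)))
    return out
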