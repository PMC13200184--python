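"""Molecular graphs, atom typing and Buckingham-class force-field evaluation.

The force field is pair-specific (no combining rules): every ordered type pair
carries its own short-range repulsion ``A*exp(-b*r)``, dispersion ``-C6/r^6``
(optionally ``-C8/r^8``) and, when charges are enabled, a point-charge Coulomb
term.  Bonded interactions are harmonic bonds and angles plus a cosine-series
dihedral.  Energies are kcal/mol, lengths Angstrom, charges e.

Two atom-typing schemes for cyclohexene-class molecules are provided: a *neat*
scheme (2 carbon + 2 hydrogen types, distinguishing only sp2 from sp3 carbon)
and a *hydrated* scheme (3 + 3 types, further splitting sp3 carbon into
allylic and homoallylic).  The extra types exist because repulsion and partial
charges are strongly coupled: a charged model needs one repulsion term per
distinct charge environment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_MASSES, COULOMB_KCAL_A_E2

OVERLAP_FLOOR = 0.1  # Angstrom; closer pairs are a degenerate geometry


class DegenerateGeometryError(ValueError):
    """Two atoms closer than the overlap floor."""


class MissingParameterError(KeyError):
    """A type pair / bonded tuple present in the system has no parameters."""


class TypingError(ValueError):
    """Atom-typing rule cannot classify an atom."""


# ---------------------------------------------------------------------------
# Molecular graph
# ---------------------------------------------------------------------------

@dataclass
class MolecularGraph:
    """Chemical graph: element per atom plus an undirected bond list.

    ``sp2_atoms`` may be given explicitly (e.g. from bond orders); otherwise
    carbons of degree 3 are taken as sp2, degree 4 as sp3.
    """

    elements: list[str]
    bonds: list[tuple[int, int]]
    sp2_atoms: frozenset[int] | None = None

    def __post_init__(self) -> None:
        canon = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            canon.add((min(i, j), max(i, j)))
        if len(canon) != len(self.bonds):
            raise ValueError("duplicate bonds in graph")
        self.bonds = sorted(canon)
        n = len(self.elements)
        if any(i >= n or i < 0 for b in self.bonds for i in b):
            raise ValueError("bond index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self) -> list[list[int]]:
        nb: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            nb[i].append(j)
            nb[j].append(i)
        return [sorted(x) for x in nb]

    def degree(self, i: int) -> int:
        return sum(1 for b in self.bonds if i in b)

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return True
        nb = self.neighbors()
        seen = {0}
        stack = [0]
        while stack:
            for j in nb[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_atoms

    def angles(self) -> list[tuple[int, int, int]]:
        """All i-j-k bonded angles, canonical (i < k)."""
        nb = self.neighbors()
        out = []
        for j in range(self.n_atoms):
            for i, k in itertools.combinations(nb[j], 2):
                out.append((i, j, k))
        return out

    def dihedrals(self) -> list[tuple[int, int, int, int]]:
        """All proper dihedrals i-j-k-l, canonical under reversal."""
        nb = self.neighbors()
        out = set()
        for j, k in self.bonds:
            for i in nb[j]:
                if i == k:
                    continue
                for l in nb[k]:
                    if l == j or l == i:
                        continue
                    quad = (i, j, k, l)
                    out.add(min(quad, quad[::-1]))
        return sorted(out)

    def carbon_roles(self) -> dict[int, str]:
        """Classify carbons as sp2 / allylic / homoallylic sp3.

        Allylic means an sp3 carbon bonded to an sp2 carbon.
        """
        nb = self.neighbors()
        if self.sp2_atoms is not None:
            sp2 = set(self.sp2_atoms)
        else:
            sp2 = set()
            for i, el in enumerate(self.elements):
                if el != "C":
                    continue
                deg = len(nb[i])
                if deg == 3:
                    sp2.add(i)
                elif deg != 4:
                    raise TypingError(
                        f"carbon {i} has degree {deg}; cannot infer hybridization"
                    )
        roles = {}
        for i, el in enumerate(self.elements):
            if el != "C":
                continue
            if i in sp2:
                roles[i] = "sp2"
            elif any(j in sp2 for j in nb[i]):
                roles[i] = "allylic"
            else:
                roles[i] = "homoallylic"
        return roles

    @classmethod
    def cyclohexene(cls) -> "MolecularGraph":
        """C6H10 ring: C0=C1 double bond, C2..C5 saturated, 10 hydrogens."""
        elements = ["C"] * 6 + ["H"] * 10
        bonds = [(i, (i + 1) % 6) for i in range(6)]
        h = 6
        for c in range(6):
            n_h = 1 if c in (0, 1) else 2
            for _ in range(n_h):
                bonds.append((c, h))
                h += 1
        return cls(elements=elements, bonds=bonds, sp2_atoms=frozenset({0, 1}))


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomTypeScheme:
    """Maps graph positions to type labels.

    ``neat``: carbons split only into sp2 (CD) vs sp3 (CS); hydrogens follow
    their carbon (HD/HS).  ``hydrated``: sp3 carbons further split into
    allylic (CA) and homoallylic (CB); hydrogens follow (HD/HA/HB).
    """

    name: str

    _CARBON = {
        "neat": {"sp2": "CD", "allylic": "CS", "homoallylic": "CS"},
        "hydrated": {"sp2": "CD", "allylic": "CA", "homoallylic": "CB"},
    }
    _HYDROGEN = {
        "neat": {"sp2": "HD", "allylic": "HS", "homoallylic": "HS"},
        "hydrated": {"sp2": "HD", "allylic": "HA", "homoallylic": "HB"},
    }

    def __post_init__(self) -> None:
        if self.name not in ("neat", "hydrated"):
            raise ValueError(f"unknown typing scheme {self.name!r}")


NEAT_SCHEME = AtomTypeScheme("neat")
HYDRATED_SCHEME = AtomTypeScheme("hydrated")


def assign_atom_types(graph: MolecularGraph, scheme: AtomTypeScheme) -> list[str]:
    """Per-atom type labels under a typing scheme.

    Purely structural, so symmetric atoms (graph automorphisms) necessarily
    receive identical labels and permuting the atoms permutes the labels.
    """
    roles = graph.carbon_roles()
    nb = graph.neighbors()
    cmap = AtomTypeScheme._CARBON[scheme.name]
    hmap = AtomTypeScheme._HYDROGEN[scheme.name]
    labels = []
    for i, el in enumerate(graph.elements):
        if el == "C":
            labels.append(cmap[roles[i]])
        elif el == "H":
            parents = [j for j in nb[i] if graph.elements[j] == "C"]
            if len(parents) != 1:
                raise TypingError(f"hydrogen {i} not bonded to exactly one carbon")
            labels.append(hmap[roles[parents[0]]])
        else:
            raise TypingError(f"element {el!r} not covered by scheme {scheme.name!r}")
    return labels


def bond_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def angle_key(a: str, b: str, c: str) -> tuple[str, str, str]:
    return min((a, b, c), (c, b, a))


def dihedral_key(a: str, b: str, c: str, d: str) -> tuple[str, str, str, str]:
    return min((a, b, c, d), (d, c, b, a))


@dataclass
class BondedTerms:
    """Distinct bonded term types present in a labelled graph."""

    bond_types: list[tuple[str, str]]
    angle_types: list[tuple[str, str, str]]
    dihedral_types: list[tuple[str, str, str, str]]
    bond_instances: list[tuple[int, int]]
    angle_instances: list[tuple[int, int, int]]
    dihedral_instances: list[tuple[int, int, int, int]]

    @property
    def n_bond_types(self) -> int:
        return len(self.bond_types)


def enumerate_bonded_terms(graph: MolecularGraph, labels: list[str]) -> BondedTerms:
    """Count and list the distinct bond / angle / dihedral type tuples."""
    if len(labels) != graph.n_atoms:
        raise ValueError("labels missing for some atoms")
    bt = sorted({bond_key(labels[i], labels[j]) for i, j in graph.bonds})
    angles = graph.angles()
    at = sorted({angle_key(labels[i], labels[j], labels[k]) for i, j, k in angles})
    dihedrals = graph.dihedrals()
    dt = sorted({dihedral_key(*(labels[x] for x in q)) for q in dihedrals})
    return BondedTerms(bt, at, dt, list(graph.bonds), angles, dihedrals)


# ---------------------------------------------------------------------------
# Force-field parameters
# ---------------------------------------------------------------------------

@dataclass
class PairParams:
    A: float = 0.0    # kcal/mol
    b: float = 3.0    # 1/Angstrom
    C6: float = 0.0   # kcal A^6/mol
    C8: float = 0.0   # kcal A^8/mol

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("Buckingham decay b must be positive")


@dataclass
class ForceFieldParams:
    """Pair-specific nonbonded + bonded parameters.

    ``pairs`` is keyed by the sorted type-label pair; there is deliberately no
    combining rule, every pair is independent.  ``scale_14`` multiplies both
    the van der Waals and Coulomb interaction of atoms three bonds apart;
    1-2 and 1-3 intramolecular pairs are always excluded.
    """

    pairs: dict[tuple[str, str], PairParams] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)
    bonds: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    dihedrals: dict[tuple[str, str, str, str], tuple[float, ...]] = field(default_factory=dict)
    charges_enabled: bool = True
    dispersion_frozen: bool = True
    scale_14: float = 1.0

    def pair(self, a: str, b: str) -> PairParams:
        try:
            return self.pairs[bond_key(a, b)]
        except KeyError:
            raise MissingParameterError(f"no pair parameters for ({a}, {b})")

    def charge(self, t: str) -> float:
        if not self.charges_enabled:
            return 0.0
        return self.charges.get(t, 0.0)

    def copy(self) -> "ForceFieldParams":
        return ForceFieldParams(
            pairs={k: replace(v) for k, v in self.pairs.items()},
            charges=dict(self.charges),
            bonds=dict(self.bonds),
            angles=dict(self.angles),
            dihedrals={k: tuple(v) for k, v in self.dihedrals.items()},
            charges_enabled=self.charges_enabled,
            dispersion_frozen=self.dispersion_frozen,
            scale_14=self.scale_14,
        )


# ---------------------------------------------------------------------------
# Configurations and force records
# ---------------------------------------------------------------------------

@dataclass
class Configuration:
    """Atomic coordinates with molecule assignment, typing and topology.

    ``bonds`` are global atom-index pairs covering every molecule; angles,
    dihedrals and nonbonded exclusions are derived from them.
    """

    coords: np.ndarray                 # (N, 3) Angstrom
    elements: list[str]
    molecule_id: np.ndarray            # (N,) int
    type_labels: list[str]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    box: np.ndarray | None = None      # (3,) Angstrom, orthorhombic
    periodic: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        n = self.coords.shape[0]
        if len(self.elements) != n or self.molecule_id.shape[0] != n:
            raise ValueError("inconsistent per-atom arrays")
        if len(self.type_labels) != n:
            raise ValueError("type labels missing for some atoms")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def molecules(self) -> list[np.ndarray]:
        """Atom-index arrays per molecule, in molecule-id order."""
        ids = np.unique(self.molecule_id)
        return [np.nonzero(self.molecule_id == m)[0] for m in ids]

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[el] for el in self.elements])


@dataclass
class ForceRecord:
    """Per-atom force vectors, kcal/(mol*Angstrom)."""

    forces: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)


def _displacements(coords: np.ndarray, i: np.ndarray, j: np.ndarray,
                   box: np.ndarray | None, periodic: bool) -> np.ndarray:
    dr = coords[i] - coords[j]
    if periodic and box is not None:
        dr -= box * np.round(dr / box)
    return dr


# ---------------------------------------------------------------------------
# Precomputed interaction terms (geometry cache for fitting)
# ---------------------------------------------------------------------------

@dataclass
class InteractionTerms:
    """Topology + geometry of every interaction term of one configuration.

    Geometry depends only on coordinates, so evaluating energies/forces for
    different parameter values reuses this cache (the force-matching design
    matrices are built directly from it).
    """

    config: Configuration
    # nonbonded pairs within cutoff (exclusions applied)
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_keys: list[tuple[str, str]]          # distinct type-pair keys
    pair_key_idx: np.ndarray                  # (n_pairs,) index into pair_keys
    pair_scale: np.ndarray                    # 1.0 or scale_14
    pair_dr: np.ndarray                       # (n_pairs, 3)
    pair_r: np.ndarray
    pair_qq_labels: list[tuple[str, str]]     # per distinct key: the labels
    # bonded
    bond_ij: np.ndarray                       # (n_bonds, 2)
    bond_keys: list[tuple[str, str]]
    bond_key_idx: np.ndarray
    bond_r: np.ndarray
    bond_unit: np.ndarray                     # (n_bonds, 3) unit vector i->j
    angle_ijk: np.ndarray
    angle_keys: list[tuple[str, str, str]]
    angle_key_idx: np.ndarray
    angle_theta: np.ndarray
    angle_grads: np.ndarray                   # (n_angles, 3 atoms, 3)
    dihedral_ijkl: np.ndarray
    dihedral_keys: list[tuple[str, str, str, str]]
    dihedral_key_idx: np.ndarray
    dihedral_phi: np.ndarray
    dihedral_grads: np.ndarray                # (n_dih, 4 atoms, 3)


def _exclusion_maps(n_atoms: int, bonds: list[tuple[int, int]]):
    """Sets of excluded (1-2, 1-3) and 1-4 scaled atom pairs."""
    nb: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        nb[i].add(j)
        nb[j].add(i)
    excl: set[tuple[int, int]] = set()
    pairs14: set[tuple[int, int]] = set()
    for i in range(n_atoms):
        for j in nb[i]:
            excl.add((min(i, j), max(i, j)))
            for k in nb[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
                    for l in nb[k]:
                        if l not in (i, j):
                            pairs14.add((min(i, l), max(i, l)))
    pairs14 -= excl
    return excl, pairs14


def precompute_terms(config: Configuration, cutoff: float) -> InteractionTerms:
    """Build the pair list and bonded geometry for one configuration."""
    coords = config.coords
    n = config.n_atoms
    labels = config.type_labels
    if config.periodic:
        if config.box is None:
            raise ValueError("periodic configuration requires a box")
        if cutoff > 0.5 * float(np.min(config.box)):
            raise ValueError("cutoff exceeds half the smallest box length")

    excl, pairs14 = _exclusion_maps(n, config.bonds)

    iu, ju = np.triu_indices(n, k=1)
    dr = _displacements(coords, iu, ju, config.box, config.periodic)
    r = np.linalg.norm(dr, axis=1)
    same_mol = config.molecule_id[iu] == config.molecule_id[ju]

    keep = r <= cutoff
    # drop excluded intramolecular pairs
    if excl:
        excl_mask = np.array(
            [(a, b) in excl for a, b in zip(iu.tolist(), ju.tolist())]
        )
        keep &= ~(same_mol & excl_mask)
    iu, ju, dr, r = iu[keep], ju[keep], dr[keep], r[keep]
    same_mol = same_mol[keep]

    if np.any(r < OVERLAP_FLOOR):
        k = int(np.argmin(r))
        raise DegenerateGeometryError(
            f"atoms {iu[k]} and {ju[k]} at r={r[k]:.4f} A (< {OVERLAP_FLOOR} A)"
        )

    scale = np.ones(len(r))
    if pairs14:
        mask14 = np.array(
            [(a, b) in pairs14 for a, b in zip(iu.tolist(), ju.tolist())]
        )
        scale[same_mol & mask14] = np.nan  # placeholder, filled by evaluator
    # distinct type-pair keys
    key_per_pair = [bond_key(labels[a], labels[b]) for a, b in zip(iu, ju)]
    pair_keys = sorted(set(key_per_pair))
    key_index = {k: i for i, k in enumerate(pair_keys)}
    key_idx = np.array([key_index[k] for k in key_per_pair], dtype=int)

    # --- bonds
    bond_ij = np.array(config.bonds, dtype=int).reshape(-1, 2)
    if len(config.bonds):
        bdr = _displacements(coords, bond_ij[:, 0], bond_ij[:, 1],
                             config.box, config.periodic)
        br = np.linalg.norm(bdr, axis=1)
        bunit = bdr / br[:, None]
        bkey_per = [bond_key(labels[a], labels[b]) for a, b in bond_ij]
    else:
        br = np.zeros(0)
        bunit = np.zeros((0, 3))
        bkey_per = []
    bond_keys = sorted(set(bkey_per))
    bkey_index = {k: i for i, k in enumerate(bond_keys)}
    bond_key_idx = np.array([bkey_index[k] for k in bkey_per], dtype=int)

    # --- angles (from a throwaway graph over the global bond list)
    graph = MolecularGraph(elements=list(config.elements), bonds=list(config.bonds))
    angles = graph.angles()
    angle_ijk = np.array(angles, dtype=int).reshape(-1, 3)
    if len(angles):
        u = _displacements(coords, angle_ijk[:, 0], angle_ijk[:, 1],
                           config.box, config.periodic)
        v = _displacements(coords, angle_ijk[:, 2], angle_ijk[:, 1],
                           config.box, config.periodic)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
        gi = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
        gk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
        gj = -(gi + gk)
        angle_grads = np.stack([gi, gj, gk], axis=1)
        akey_per = [angle_key(labels[a], labels[b], labels[c]) for a, b, c in angles]
    else:
        theta = np.zeros(0)
        angle_grads = np.zeros((0, 3, 3))
        akey_per = []
    angle_keys = sorted(set(akey_per))
    akey_index = {k: i for i, k in enumerate(angle_keys)}
    angle_key_idx = np.array([akey_index[k] for k in akey_per], dtype=int)

    # --- dihedrals
    dihedrals = graph.dihedrals()
    dih = np.array(dihedrals, dtype=int).reshape(-1, 4)
    if len(dihedrals):
        b1 = _displacements(coords, dih[:, 1], dih[:, 0], config.box, config.periodic)
        b2 = _displacements(coords, dih[:, 2], dih[:, 1], config.box, config.periodic)
        b3 = _displacements(coords, dih[:, 3], dih[:, 2], config.box, config.periodic)
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / nb2[:, None])
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(m1 * n2, axis=1)
        phi = np.arctan2(y, x)
        sn1 = np.sum(n1 * n1, axis=1)
        sn2 = np.sum(n2 * n2, axis=1)
        gI = (nb2 / sn1)[:, None] * n1
        gL = -(nb2 / sn2)[:, None] * n2
        p1 = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
        p3 = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
        gJ = -(1.0 + p1) * gI + p3 * gL
        gK = p1 * gI - (1.0 + p3) * gL
        dihedral_grads = np.stack([gI, gJ, gK, gL], axis=1)
        dkey_per = [dihedral_key(*(labels[x_] for x_ in q)) for q in dihedrals]
    else:
        phi = np.zeros(0)
        dihedral_grads = np.zeros((0, 4, 3))
        dkey_per = []
    dihedral_keys = sorted(set(dkey_per))
    dkey_index = {k: i for i, k in enumerate(dihedral_keys)}
    dihedral_key_idx = np.array([dkey_index[k] for k in dkey_per], dtype=int)

    return InteractionTerms(
        config=config,
        pair_i=iu, pair_j=ju,
        pair_keys=pair_keys, pair_key_idx=key_idx,
        pair_scale=scale, pair_dr=dr, pair_r=r,
        pair_qq_labels=pair_keys,
        bond_ij=bond_ij, bond_keys=bond_keys, bond_key_idx=bond_key_idx,
        bond_r=br, bond_unit=bunit,
        angle_ijk=angle_ijk, angle_keys=angle_keys, angle_key_idx=angle_key_idx,
        angle_theta=theta, angle_grads=angle_grads,
        dihedral_ijkl=dih, dihedral_keys=dihedral_keys,
        dihedral_key_idx=dihedral_key_idx,
        dihedral_phi=phi, dihedral_grads=dihedral_grads,
    )


def _accumulate_pair_forces(forces: np.ndarray, terms: InteractionTerms,
                            du_dr: np.ndarray) -> None:
    """Scatter -u'(r) * rhat onto atoms i (and the opposite onto j)."""
    fvec = -(du_dr / terms.pair_r)[:, None] * terms.pair_dr
    np.add.at(forces, terms.pair_i, fvec)
    np.add.at(forces, terms.pair_j, -fvec)


def evaluate_terms(terms: InteractionTerms, params: ForceFieldParams
                   ) -> tuple[float, ForceRecord]:
    """Energy and analytic forces for cached geometry under given parameters."""
    cfg = terms.config
    labels = cfg.type_labels
    forces = np.zeros((cfg.n_atoms, 3))
    energy = 0.0

    # nonbonded
    r = terms.pair_r
    if len(r):
        A = np.empty(len(terms.pair_keys))
        b = np.empty(len(terms.pair_keys))
        C6 = np.empty(len(terms.pair_keys))
        C8 = np.empty(len(terms.pair_keys))
        for k, key in enumerate(terms.pair_keys):
            p = params.pair(*key)
            A[k], b[k], C6[k], C8[k] = p.A, p.b, p.C6, p.C8
        qq = np.array(
            [params.charge(a) * params.charge(b_) for a, b_ in terms.pair_keys]
        ) * COULOMB_KCAL_A_E2
        ki = terms.pair_key_idx
        scale = np.where(np.isnan(terms.pair_scale), params.scale_14,
                         terms.pair_scale)
        expo = A[ki] * np.exp(-b[ki] * r)
        u = expo - C6[ki] / r**6 - C8[ki] / r**8 + qq[ki] / r
        du = -b[ki] * expo + 6 * C6[ki] / r**7 + 8 * C8[ki] / r**9 - qq[ki] / r**2
        energy += float(np.sum(scale * u))
        _accumulate_pair_forces(forces, terms, scale * du)

    # bonds: E = 0.5 k (r - r0)^2
    if len(terms.bond_r):
        r0 = np.empty(len(terms.bond_keys))
        kk = np.empty(len(terms.bond_keys))
        for k, key in enumerate(terms.bond_keys):
            try:
                r0[k], kk[k] = params.bonds[key][0], params.bonds[key][1]
            except KeyError:
                raise MissingParameterError(f"no bond parameters for {key}")
        bi = terms.bond_key_idx
        dr_ = terms.bond_r - r0[bi]
        energy += float(np.sum(0.5 * kk[bi] * dr_**2))
        f = -(kk[bi] * dr_)[:, None] * terms.bond_unit
        np.add.at(forces, terms.bond_ij[:, 0], f)
        np.add.at(forces, terms.bond_ij[:, 1], -f)

    # angles: E = 0.5 k (theta - theta0)^2
    if len(terms.angle_theta):
        t0 = np.empty(len(terms.angle_keys))
        kk = np.empty(len(terms.angle_keys))
        for k, key in enumerate(terms.angle_keys):
            try:
                t0[k], kk[k] = params.angles[key][0], params.angles[key][1]
            except KeyError:
                raise MissingParameterError(f"no angle parameters for {key}")
        ai = terms.angle_key_idx
        dt = terms.angle_theta - t0[ai]
        energy += float(np.sum(0.5 * kk[ai] * dt**2))
        coef = -(kk[ai] * dt)
        for a in range(3):
            np.add.at(forces, terms.angle_ijk[:, a],
                      coef[:, None] * terms.angle_grads[:, a, :])

    # dihedrals: E = sum_n c_n cos(n phi)
    if len(terms.dihedral_phi):
        coeffs = []
        for key in terms.dihedral_keys:
            try:
                coeffs.append(np.asarray(params.dihedrals[key], dtype=float))
            except KeyError:
                raise MissingParameterError(f"no dihedral parameters for {key}")
        di = terms.dihedral_key_idx
        phi = terms.dihedral_phi
        dE_dphi = np.zeros_like(phi)
        for k, c in enumerate(coeffs):
            sel = di == k
            for n, cn in enumerate(c):
                energy += float(np.sum(cn * np.cos(n * phi[sel])))
                dE_dphi[sel] += -n * cn * np.sin(n * phi[sel])
        coef = -dE_dphi
        for a in range(4):
            np.add.at(forces, terms.dihedral_ijkl[:, a],
                      coef[:, None] * terms.dihedral_grads[:, a, :])

    return energy, ForceRecord(forces=forces)


def evaluate_energy_forces(config: Configuration, params: ForceFieldParams,
                           cutoff: float) -> tuple[float, ForceRecord]:
    """Total energy (kcal/mol) and exact-gradient forces (kcal/(mol*A))."""
    terms = precompute_terms(config, cutoff)
    return evaluate_terms(terms, params)


# ---------------------------------------------------------------------------
# Molecular net forces and torques
# ---------------------------------------------------------------------------

def molecular_force_torque(record: ForceRecord, config: Configuration
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule net force and torque about the molecular center of mass.

    Net force: kcal/(mol*A); torque: kcal/mol.  Returned in molecule-id order.
    """
    masses = config.masses()
    nets, torques = [], []
    for idx in config.molecules:
        if len(idx) == 0:
            raise ValueError("molecule with zero atoms")
        f = record.forces[idx]
        m = masses[idx]
        com = np.sum(m[:, None] * config.coords[idx], axis=0) / np.sum(m)
        nets.append(np.sum(f, axis=0))
        torques.append(np.sum(np.cross(config.coords[idx] - com, f), axis=0))
    return np.array(nets), np.array(torques)


# ---------------------------------------------------------------------------
# Tabulated potentials (GROMACS user-table dialect)
# ---------------------------------------------------------------------------

def tabulated_potential_columns(pair: PairParams, qq: float, r_grid: np.ndarray
                                ) -> np.ndarray:
    """7-column table: r, f, -f', g, -g', h, -h'.

    f is the scaled Coulomb component ke*qq/r, g the dispersion
    -C6/r^6 - C8/r^8 and h the repulsion A*exp(-b r); derivative columns are
    analytic.  ``qq`` is the charge product q_i*q_j in e^2.
    """
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or len(r) < 2 or np.any(np.diff(r) <= 0):
        raise ValueError("r grid must be strictly increasing")
    if r[0] <= OVERLAP_FLOOR:
        raise ValueError(f"r grid must start above the overlap floor {OVERLAP_FLOOR} A")
    ke_qq = COULOMB_KCAL_A_E2 * qq
    f = ke_qq / r
    mfp = ke_qq / r**2                       # -f'
    g = -pair.C6 / r**6 - pair.C8 / r**8
    mgp = -6 * pair.C6 / r**7 - 8 * pair.C8 / r**9   # -g'
    h = pair.A * np.exp(-pair.b * r)
    mhp = pair.A * pair.b * np.exp(-pair.b * r)      # -h'
    return np.column_stack([r, f, mfp, g, mgp, h, mhp])


def write_tabulated_potential(pair: PairParams, qq: float, r_grid: np.ndarray,
                              path) -> None:
    """Write the 7-column whitespace table to ``path``."""
    table = tabulated_potential_columns(pair, qq, r_grid)
    header = ("tabulated pair potential: r[A]  f  -f'  g  -g'  h  -h'\n"
              f"A={pair.A:.10g} b={pair.b:.10g} C6={pair.C6:.10g} "
              f"C8={pair.C8:.10g} qq={qq:.10g}")
    np.savetxt(path, table, fmt="%.12e", header=header)


def read_tabulated_potential(path) -> np.ndarray:
    return np.loadtxt(path)
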