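"""Topology and geometry of FN dimers and the growing fibril network.

An FN dimer is a chain of 30 elastic Type III domain springs (domains
III_1..III_15 of monomer A followed by III_15..III_1 of monomer B) with an
inelastic Type I/II connector at each end and integrin sites at the two
III_10 positions (chain positions 10 and 21).  A fibril is a tree of such
dimers rooted at a substrate-bound molecule: each soluble dimer joins the
network by binding its N-terminal connector to an exposed cryptic site of a
perimeter molecule.  The mechanical model is one-dimensional along z; the
x-y cross-section is hexagonal-lattice packing bookkeeping that determines
which molecules sit on the fibril perimeter.

This module holds no kinetics and no force laws - only structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import IllegalBindError, InvalidProfileError, InvalidSiteError
from .params import ModelParams

SUBSTRATE = "SUBSTRATE"

#: Integrin (III_10) chain positions of a dimer.
INTEGRIN_POSITIONS = (10, 21)

#: Axial-coordinate offsets of the six hexagonal neighbors, in CCW order
#: starting from the +x direction.
HEX_NEIGHBORS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def domain_index(position: int) -> int:
    """Map chain position 1..30 to Type III domain index 1..15 (mirrored)."""
    if not 1 <= position <= 30:
        raise ValueError("chain position must be in 1..30")
    return position if position <= 15 else 31 - position


@dataclass(frozen=True)
class DomainSpec:
    """Static properties of one Type III domain."""
    index: int                 #: domain number 1..15
    k0: float                  #: resting stiffness, pN/nm
    has_cryptic_site: bool = False

    def __post_init__(self):
        if not 1 <= self.index <= 15:
            raise InvalidSiteError(f"domain index {self.index} outside 1..15")
        if not 0.2 - 1e-12 <= self.k0 <= 1.0 + 1e-12:
            raise InvalidProfileError(
                f"resting stiffness {self.k0} outside [0.2, 1.0] pN/nm")


@dataclass
class DomainState:
    """Dynamic state of one domain spring."""
    stretch: float = 0.0       #: extension beyond rest length, nm
    exposed: bool = False      #: cryptic site currently exposed
    occupied: bool = False     #: a soluble FN bound here (irreversible)


@dataclass
class FNMolecule:
    """One FN dimer: 30 domain springs plus two inelastic end connectors.

    ``chain[p - 1]`` is the :class:`DomainSpec` at chain position p; the
    profile is mirrored so positions p and 31-p reference the same domain.
    """
    id: int
    chain: list            #: 30 DomainSpec, mirrored profile
    states: list           #: 30 DomainState
    lattice_coord: Optional[tuple] = None   #: axial (q, r) in the cross-section
    attachment: object = SUBSTRATE          #: SUBSTRATE or (parent id, parent pos)
    node_start: int = -1   #: index of this molecule's position-1 node in Fibril arrays

    integrin_site_positions = INTEGRIN_POSITIONS
    n_term_connectors = 2

    def spec(self, position: int) -> DomainSpec:
        return self.chain[position - 1]

    def state(self, position: int) -> DomainState:
        return self.states[position - 1]


@dataclass(frozen=True)
class IntegrinBond:
    """A bound molecular clutch at one III_10 site."""
    molecule_id: int
    site_position: int         #: 10 or 21
    extension: float           #: clutch extension, nm (>= 0)
    f_clutch: float            #: k_c * extension, pN


def build_dimer(profile: Sequence[DomainSpec], site_set: Iterable[int],
                mol_id: int = 0) -> FNMolecule:
    """Build one FN dimer from a 15-domain profile and a cryptic-site set.

    ``profile[i]`` supplies the resting stiffness of domain i+1; the
    returned molecule carries the mirrored 30-position chain with
    ``has_cryptic_site`` set wherever the position's domain index is in
    ``site_set``.  All domain states start at zero stretch, unexposed and
    unoccupied.
    """
    profile = list(profile)
    if len(profile) != 15:
        raise InvalidProfileError(
            f"stiffness profile must have 15 entries, got {len(profile)}")
    indices = sorted(spec.index for spec in profile)
    if indices != list(range(1, 16)):
        raise InvalidProfileError("profile domain indices must be exactly 1..15")
    site_set = set(site_set)
    bad = site_set - set(range(1, 16))
    if bad:
        raise InvalidSiteError(f"cryptic site indices outside 1..15: {sorted(bad)}")
    by_index = {spec.index: spec for spec in profile}
    chain = []
    for pos in range(1, 31):
        d = domain_index(pos)
        base = by_index[d]
        chain.append(DomainSpec(index=d, k0=base.k0,
                                has_cryptic_site=d in site_set))
    states = [DomainState() for _ in range(30)]
    return FNMolecule(id=mol_id, chain=chain, states=states)


def make_profile(k0_values: Sequence[float]) -> list:
    """Turn a 15-vector of resting stiffnesses into a DomainSpec profile."""
    if len(k0_values) != 15:
        raise InvalidProfileError("need exactly 15 stiffness values")
    return [DomainSpec(index=i + 1, k0=float(k)) for i, k in enumerate(k0_values)]


# ---------------------------------------------------------------------------
# Hexagonal lattice helpers (axial coordinates, pointy-top)
# ---------------------------------------------------------------------------

def axial_to_xy(coord: tuple, d_lat: float = 1.0) -> tuple:
    """Cartesian center of an axial (q, r) site at lattice spacing d_lat."""
    q, r = coord
    return (d_lat * (q + 0.5 * r), d_lat * (math.sqrt(3.0) / 2.0) * r)


def hex_neighbors(coord: tuple) -> list:
    q, r = coord
    return [(q + dq, r + dr) for dq, dr in HEX_NEIGHBORS]


@lru_cache(maxsize=64)
def _ring_offsets(k: int) -> tuple:
    """Axial offsets at hex distance k, sorted by CCW angle from +x."""
    if k == 0:
        return ((0, 0),)
    offsets = []
    for q in range(-k, k + 1):
        for r in range(max(-k, -q - k), min(k, -q + k) + 1):
            if max(abs(q), abs(r), abs(q + r)) == k:
                offsets.append((q, r))
    def angle(off):
        x, y = axial_to_xy(off)
        a = math.atan2(y, x)
        return a if a >= -1e-12 else a + 2.0 * math.pi
    offsets.sort(key=lambda off: (angle(off),))
    return tuple(offsets)


def nearest_free_site(occupied, center: tuple) -> tuple:
    """Nearest unoccupied lattice site to ``center``, deterministically.

    Candidates are compared by Euclidean distance between site centers;
    ties break on (ring number, CCW angular index within the ring), so a
    given occupancy pattern always yields the same placement.
    """
    best = None  # (dist, ring, idx, coord)
    k = 1
    while True:
        # Once every site of ring k is farther than the current best,
        # no larger ring can win: ring distances grow at least as
        # sqrt(3)/2 * k * d.
        if best is not None and (math.sqrt(3.0) / 2.0) * k > best[0] + 1e-12:
            return best[3]
        for idx, (dq, dr) in enumerate(_ring_offsets(k)):
            coord = (center[0] + dq, center[1] + dr)
            if coord in occupied:
                continue
            x, y = axial_to_xy((dq, dr))
            dist = math.hypot(x, y)
            cand = (dist, k, idx, coord)
            if best is None or cand[:3] < best[:3]:
                best = cand
        k += 1
        if k > 200:  # pragma: no cover - safety net
            raise RuntimeError("no free lattice site found within 200 rings")


# ---------------------------------------------------------------------------
# Fibril
# ---------------------------------------------------------------------------

@dataclass
class FnBond:
    """An irreversible FN-FN bond (parent exposed site -> child N-terminus)."""
    parent_id: int
    parent_position: int
    child_id: int


class Fibril:
    """The growing FN network: molecules, bonds, lattice and node arrays.

    Mechanical state is stored in flat per-node arrays so the equilibrium
    solver can run over them directly.  Node 0 is the root molecule's base
    (the far end of the substrate spring); molecule m then contributes 30
    consecutive nodes for chain positions 1..30, each the distal junction
    of its domain spring.  A child's position-1 spring is anchored at its
    parent's exposed-domain node with the inelastic connector length folded
    into that spring's rest length.
    """

    _GROW = 64 * 30

    def __init__(self, profile: Sequence[DomainSpec], site_set: Iterable[int],
                 params: ModelParams):
        self.params = params
        self.profile = list(profile)
        self.site_set = frozenset(site_set)
        self.molecules: list[FNMolecule] = []
        self.fn_bonds: list[FnBond] = []
        self.lattice: dict = {}
        self._perimeter: set = set()
        self.actin_z: float = 0.0

        cap = 1 + self._GROW
        self.node_parent = np.full(cap, -1, dtype=np.int64)
        self.spring_k0 = np.zeros(cap)
        self.spring_rest = np.zeros(cap)
        self.spring_linear = np.zeros(cap, dtype=bool)
        self.rest_z = np.zeros(cap)
        self.z = np.zeros(cap)
        self.cryptic = np.zeros(cap, dtype=bool)
        self.exposed = np.zeros(cap, dtype=bool)
        self.occupied = np.zeros(cap, dtype=bool)
        self.node_mol = np.full(cap, -1, dtype=np.int64)
        self.node_pos = np.zeros(cap, dtype=np.int64)
        self.n_nodes = 0

        # Integrin bonds: per molecule x site {10, 21}
        mcap = cap // 30 + 1
        self.bond_active = np.zeros((mcap, 2), dtype=bool)
        self.bond_offset = np.zeros((mcap, 2))

        # Substrate node: linear spring k_sub to ground, connector length
        # folded into the rest length so x_sub = z[0] - l_I_II.
        i = self._new_node()
        self.node_parent[i] = -1
        self.spring_k0[i] = params.k_sub
        self.spring_rest[i] = params.l_I_II
        self.spring_linear[i] = True
        self.rest_z[i] = params.l_I_II
        self.z[i] = params.l_I_II

        root = build_dimer(self.profile, self.site_set, mol_id=0)
        root.attachment = SUBSTRATE
        root.lattice_coord = (0, 0)
        self._append_molecule(root, parent_node=0, connector=0.0)
        self.lattice[(0, 0)] = 0
        self._perimeter.add(0)
        self.actin_z = self.stretched_tip()

    # -- construction helpers ------------------------------------------------

    def _new_node(self) -> int:
        if self.n_nodes >= len(self.z):
            self._grow_arrays()
        i = self.n_nodes
        self.n_nodes += 1
        return i

    def _grow_arrays(self) -> None:
        new_cap = len(self.z) + self._GROW
        for name in ("node_parent", "spring_k0", "spring_rest", "spring_linear",
                     "rest_z", "z", "cryptic", "exposed", "occupied",
                     "node_mol", "node_pos"):
            old = getattr(self, name)
            arr = np.zeros(new_cap, dtype=old.dtype)
            if name in ("node_parent", "node_mol"):
                arr[:] = -1
            arr[:len(old)] = old
            setattr(self, name, arr)
        mcap = new_cap // 30 + 1
        for name, width in (("bond_active", 2), ("bond_offset", 2)):
            old = getattr(self, name)
            arr = np.zeros((mcap, width), dtype=old.dtype)
            arr[:len(old)] = old
            setattr(self, name, arr)

    def _append_molecule(self, mol: FNMolecule, parent_node: int,
                         connector: float) -> None:
        """Add a dimer's 30 nodes, anchored at ``parent_node``."""
        p = self.params
        mol.node_start = self.n_nodes
        prev = parent_node
        for pos in range(1, 31):
            i = self._new_node()
            spec = mol.chain[pos - 1]
            self.node_parent[i] = prev
            self.spring_k0[i] = spec.k0
            rest = p.l_III + (connector if pos == 1 else 0.0)
            self.spring_rest[i] = rest
            self.rest_z[i] = self.rest_z[prev] + rest
            self.z[i] = self.z[prev] + rest
            self.cryptic[i] = spec.has_cryptic_site
            self.node_mol[i] = mol.id
            self.node_pos[i] = pos
            prev = i
        self.molecules.append(mol)

    # -- indexing ------------------------------------------------------------

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def node_of(self, mol_id: int, position: int) -> int:
        """Global node index of (molecule, chain position)."""
        if not 1 <= position <= 30:
            raise ValueError("chain position must be in 1..30")
        return self.molecules[mol_id].node_start + position - 1

    @property
    def x_sub(self) -> float:
        """Substrate spring extension, nm."""
        return float(self.z[0] - self.params.l_I_II)

    @property
    def f_sub(self) -> float:
        """Substrate force k_sub * x_sub, pN."""
        return self.params.k_sub * self.x_sub

    def stretched_tip(self) -> float:
        """Current maximum z extent, nm, including the distal connector."""
        return float(self.z[:self.n_nodes].max() + self.params.l_I_II)

    def relaxed_tip(self) -> float:
        """Maximum z extent with every spring at rest, nm."""
        return float(self.rest_z[:self.n_nodes].max() + self.params.l_I_II)

    # -- integrin bonds ------------------------------------------------------

    def integrin_sites(self, mol_id: int):
        """(site index 0/1, chain position, node, bound?) for one molecule."""
        out = []
        for s, pos in enumerate(INTEGRIN_POSITIONS):
            out.append((s, pos, self.node_of(mol_id, pos),
                        bool(self.bond_active[mol_id, s])))
        return out

    def bind_integrin(self, mol_id: int, site: int) -> None:
        node = self.node_of(mol_id, INTEGRIN_POSITIONS[site])
        self.bond_active[mol_id, site] = True
        self.bond_offset[mol_id, site] = self.actin_z - self.z[node]

    def unbind_integrin(self, mol_id: int, site: int) -> None:
        self.bond_active[mol_id, site] = False
        self.bond_offset[mol_id, site] = 0.0

    def clear_integrins(self) -> None:
        self.bond_active[:] = False
        self.bond_offset[:] = 0.0

    @property
    def n_integrins(self) -> int:
        return int(self.bond_active[:self.n_molecules].sum())

    def integrin_bonds(self) -> list:
        """Snapshot of all bound clutches as :class:`IntegrinBond`."""
        out = []
        for m in range(self.n_molecules):
            for s, pos in enumerate(INTEGRIN_POSITIONS):
                if self.bond_active[m, s]:
                    node = self.node_of(m, pos)
                    ext = max(0.0, self.actin_z - self.z[node]
                              - self.bond_offset[m, s])
                    out.append(IntegrinBond(m, pos, ext, self.params.k_c * ext))
        return out

    # -- growth --------------------------------------------------------------

    def attach_soluble_fn(self, parent_id: int, parent_position: int) -> FNMolecule:
        """Bind a soluble dimer at an exposed, unoccupied perimeter site.

        The new molecule's N-terminal connector joins the parent's domain
        node; it takes the free lattice site nearest the parent and enters
        mechanically at rest.
        """
        node = self.node_of(parent_id, parent_position)
        if not self.exposed[node] or self.occupied[node]:
            raise IllegalBindError(
                f"position {parent_position} of molecule {parent_id} is not "
                "an exposed, unoccupied cryptic site")
        if parent_id not in self._perimeter:
            raise IllegalBindError(
                f"molecule {parent_id} is not on the fibril perimeter")
        parent_coord = self.molecules[parent_id].lattice_coord
        coord = nearest_free_site(self.lattice, parent_coord)
        child_id = self.n_molecules
        child = build_dimer(self.profile, self.site_set, mol_id=child_id)
        child.attachment = (parent_id, parent_position)
        child.lattice_coord = coord
        self._append_molecule(child, parent_node=node,
                              connector=self.params.l_I_II)
        self.occupied[node] = True
        self.lattice[coord] = child_id
        self.fn_bonds.append(FnBond(parent_id, parent_position, child_id))
        self._update_perimeter_around(coord)
        return child

    def _update_perimeter_around(self, coord: tuple) -> None:
        for c in [coord] + hex_neighbors(coord):
            mol = self.lattice.get(c)
            if mol is None:
                continue
            if any(n not in self.lattice for n in hex_neighbors(c)):
                self._perimeter.add(mol)
            else:
                self._perimeter.discard(mol)

    def perimeter_molecules(self) -> set:
        """Molecules whose lattice site has a free hexagonal neighbor."""
        return set(self._perimeter)

    # -- state views ---------------------------------------------------------

    def stretches(self) -> np.ndarray:
        """Per-node spring extension beyond rest, nm (index 1..n_nodes-1)."""
        n = self.n_nodes
        s = np.zeros(n)
        par = self.node_parent[1:n]
        s[1:] = self.z[1:n] - self.z[par] - self.spring_rest[1:n]
        s[0] = self.z[0] - self.spring_rest[0]
        return s

    def domain_state(self, mol_id: int, position: int) -> DomainState:
        node = self.node_of(mol_id, position)
        return DomainState(stretch=float(self.stretches()[node]),
                           exposed=bool(self.exposed[node]),
                           occupied=bool(self.occupied[node]))

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        """Raise if a structural invariant is violated (debug/testing aid)."""
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(m.id for m in self.molecules)
        g.add_edges_from((b.parent_id, b.child_id) for b in self.fn_bonds)
        if g.number_of_nodes() and not nx.is_tree(g):
            from .errors import TopologyError
            raise TopologyError("FN-FN bond graph is not a single tree")
        assert len(self.lattice) == self.n_molecules, \
            "lattice occupancy must equal molecule count"
        coords = [m.lattice_coord for m in self.molecules]
        assert len(set(coords)) == len(coords), "lattice coords must be unique"
        for m in self.molecules:
            for pos in range(1, 16):
                assert m.spec(pos).k0 == m.spec(31 - pos).k0, \
                    "mirror symmetry of the stiffness profile"

    # -- copy ----------------------------------------------------------------

    def copy(self) -> "Fibril":
        import copy as _copy
        new = object.__new__(Fibril)
        new.params = self.params
        new.profile = list(self.profile)
        new.site_set = self.site_set
        new.molecules = _copy.deepcopy(self.molecules)
        new.fn_bonds = _copy.deepcopy(self.fn_bonds)
        new.lattice = dict(self.lattice)
        new._perimeter = set(self._perimeter)
        new.actin_z = self.actin_z
        new.n_nodes = self.n_nodes
        for name in ("node_parent", "spring_k0", "spring_rest", "spring_linear",
                     "rest_z", "z", "cryptic", "exposed", "occupied",
                     "node_mol", "node_pos", "bond_active", "bond_offset"):
            setattr(new, name, getattr(self, name).copy())
        return new


def brute_force_perimeter(fibril: Fibril) -> set:
    """Exhaustive O(N*6) perimeter scan - the oracle for perimeter_molecules."""
    out = set()
    for coord, mol in fibril.lattice.items():
        if any(n not in fibril.lattice for n in hex_neighbors(coord)):
            out.add(mol)
    return out
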