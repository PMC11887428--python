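"""Molecular data model used by every stage of the assignment workflow.

A :class:`Molecule` is an ordered list of atoms with explicit hydrogens,
a bond list with integer orders, and stereo descriptors computed once from
the input geometry.  Atom indexing is 0-based internally; file formats keep
their native 1-based serials at the I/O boundary (see :mod:`glyccs.io`).

Hydrogens are never added implicitly: the charge-enumeration stage moves
protons around, so implicit-hydrogen ambiguity is unacceptable and inputs
must carry explicit H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
from rdkit import Chem
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "RotatableBondSet",
    "UnknownElementError",
    "monoisotopic_mass",
    "find_rotatable_bonds",
    "perceive_bonds",
    "assign_stereo",
    "covalent_radius",
    "vdw_radius",
    "element_mass",
]

_PT = Chem.GetPeriodicTable()

# Distance-based bond perception (XYZ, bond-less PDB): two atoms are bonded
# iff their distance is below this multiple of the sum of covalent radii.
BOND_PERCEPTION_FACTOR = 1.3


class UnknownElementError(ValueError):
    """Raised when an element symbol has no tabulated mass/radii."""

    def __init__(self, symbol: str):
        super().__init__(f"unknown element symbol: {symbol!r}")
        self.symbol = symbol


def _atomic_number(symbol: str) -> int:
    try:
        z = _PT.GetAtomicNumber(symbol)
    except Exception:
        raise UnknownElementError(symbol) from None
    if z <= 0:
        raise UnknownElementError(symbol)
    return z


def element_mass(symbol: str) -> float:
    """Principal-isotope (monoisotopic) mass of an element in Da."""
    return _PT.GetMostCommonIsotopeMass(_atomic_number(symbol))


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Å (RDKit periodic-table values)."""
    return _PT.GetRcovalent(_atomic_number(symbol))


def vdw_radius(symbol: str) -> float:
    """van der Waals radius in Å (RDKit periodic-table values)."""
    return _PT.GetRvdw(_atomic_number(symbol))


@dataclass
class Atom:
    element: str
    position: np.ndarray
    formal_charge: int = 0
    partial_charge: float = 0.0

    def __post_init__(self):
        _atomic_number(self.element)  # validate symbol early
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"invalid position for {self.element}: {self.position}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def atomic_number(self) -> int:
        return _atomic_number(self.element)

    def copy(self) -> "Atom":
        return Atom(self.element, self.position.copy(), self.formal_charge, self.partial_charge)


class Bond(NamedTuple):
    i: int
    j: int
    order: int = 1


@dataclass
class Molecule:
    atoms: list[Atom]
    bonds: list[Bond]
    stereo: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond {b} references atom outside 0..{n - 1}")
            if b.i == b.j:
                raise ValueError(f"self-loop bond {b}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    # -- basic views ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, coords):
            a.position = p.copy()

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def partial_charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def set_partial_charges(self, q: Iterable[float]) -> None:
        q = list(q)
        if len(q) != self.n_atoms:
            raise ValueError("partial charge list length mismatch")
        for a, qi in zip(self.atoms, q):
            a.partial_charge = float(qi)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element, formal_charge=a.formal_charge)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        return g

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return sorted(out)

    def copy(self) -> "Molecule":
        return Molecule(
            [a.copy() for a in self.atoms],
            list(self.bonds),
            {k: dict(v) for k, v in self.stereo.items()},
            self.label,
        )

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        m = self.copy()
        m.set_coords(coords)
        return m


def monoisotopic_mass(m: Molecule) -> float:
    """Sum of principal-isotope masses in Da.

    The electron mass is ignored for ions (neutral-atom masses are summed
    regardless of formal charges); at the precision used here (1e-4 Da
    tolerances) this convention is stated rather than corrected for.
    """
    return float(sum(element_mass(a.element) for a in m.atoms))


def perceive_bonds(atoms: list[Atom]) -> list[Bond]:
    """Distance-based single-bond perception.

    Two atoms are bonded iff their separation is below
    ``BOND_PERCEPTION_FACTOR`` x (sum of covalent radii).  Used as the
    fallback for XYZ files and PDB records without CONECT entries; orders
    are all 1 (the workflow never needs perceived multiple bonds).
    """
    if len(atoms) < 2:
        return []
    coords = np.array([a.position for a in atoms])
    radii = np.array([covalent_radius(a.element) for a in atoms])
    tree = cKDTree(coords)
    cutoff = BOND_PERCEPTION_FACTOR * 2.0 * radii.max()
    bonds = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        d = np.linalg.norm(coords[i] - coords[j])
        if d < BOND_PERCEPTION_FACTOR * (radii[i] + radii[j]):
            bonds.append(Bond(i, j, 1))
    return bonds


# -- stereo perception ----------------------------------------------------


def _priority_signature(g: nx.Graph, start: int, blocked: int, elements: list[str], depth: int = 6):
    """CIP-like substituent priority: atomic numbers collected per BFS shell,
    starting at `start` and never stepping back onto `blocked`."""
    sig = []
    frontier = [start]
    visited = {blocked, start}
    for _ in range(depth):
        sig.append(tuple(sorted((_atomic_number(elements[n]) for n in frontier), reverse=True)))
        nxt = []
        for n in frontier:
            for nb in g.neighbors(n):
                if nb not in visited:
                    visited.add(nb)
                    nxt.append(nb)
        if not nxt:
            break
        frontier = nxt
    return tuple(sig)


def assign_stereo(m: Molecule) -> dict:
    """Compute stereo descriptors from the current geometry.

    Tetrahedral centers: atoms with four neighbors whose priority signatures
    are pairwise distinct get an R/S-like label from the signed volume of the
    three highest-priority substituent vectors.  Double bonds with distinct
    substituents on both ends get E/Z from the corresponding dihedral.

    The labels follow a fixed internal convention (atomic number + graph
    traversal priorities), not full CIP rules; they are stable under
    conformational change and invert only if the geometry truly inverts,
    which is what the pipeline asserts on.
    """
    g = m.graph()
    elements = m.elements
    coords = m.coords
    tet: dict[int, str] = {}
    for i in range(m.n_atoms):
        nbrs = sorted(g.neighbors(i))
        if len(nbrs) != 4:
            continue
        sigs = {n: _priority_signature(g, n, i, elements) for n in nbrs}
        if len(set(sigs.values())) != 4:
            continue
        ordered = sorted(nbrs, key=lambda n: sigs[n], reverse=True)
        v = [coords[n] - coords[i] for n in ordered[:3]]
        vol = float(np.dot(v[0], np.cross(v[1], v[2])))
        tet[i] = "R" if vol < 0 else "S"

    ez: dict[tuple[int, int], str] = {}
    for b in m.bonds:
        if b.order != 2:
            continue
        ends = []
        for end, other in ((b.i, b.j), (b.j, b.i)):
            subs = [n for n in g.neighbors(end) if n != other]
            if not subs:
                break
            sigs = {n: _priority_signature(g, n, end, elements) for n in subs}
            if len(subs) == 2 and sigs[subs[0]] == sigs[subs[1]]:
                break
            ends.append(max(subs, key=lambda n: sigs[n]))
        if len(ends) != 2:
            continue
        dihedral = _dihedral(coords[ends[0]], coords[b.i], coords[b.j], coords[ends[1]])
        ez[(min(b.i, b.j), max(b.i, b.j))] = "Z" if abs(dihedral) < np.pi / 2 else "E"

    return {"tetrahedral": tet, "double_bond": ez}


def stereo_parities(m: Molecule) -> dict[int, int]:
    """Geometric parity (+1/-1) of every atom with four neighbors.

    The signed volume of the first three neighbor vectors, neighbors taken
    in atom-index order.  Unlike the R/S labels this does not depend on
    substituent priorities, so it is directly comparable before and after
    a proton is added or removed elsewhere in the molecule: a parity flip
    means the geometry truly inverted.
    """
    g = m.graph()
    coords = m.coords
    out: dict[int, int] = {}
    for i in range(m.n_atoms):
        nbrs = sorted(g.neighbors(i))
        if len(nbrs) != 4:
            continue
        v = [coords[n] - coords[i] for n in nbrs[:3]]
        vol = float(np.dot(v[0], np.cross(v[1], v[2])))
        out[i] = 1 if vol > 0 else -1
    return out


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


# -- rotatable bonds ------------------------------------------------------


@dataclass
class RotatableBondSet:
    """Classification of every bond as rotatable or fixed, with reason codes.

    Codes: ``ring`` (in a cycle), ``terminal`` (to a monovalent atom or a
    locally symmetric rotor such as CH3), ``amide`` (C-N of an amide),
    ``order`` (multiple bond), ``glycosidic-exocyclic`` and ``generic``
    (rotatable).
    """

    rotatable: list[tuple[int, int]]
    reasons: dict[tuple[int, int], str]

    @property
    def n_rotatable(self) -> int:
        return len(self.rotatable)


def _is_symmetric_rotor(m: Molecule, g: nx.Graph, end: int, other: int) -> bool:
    """True when all substituents of `end` besides `other` are >=3 identical
    monovalent atoms (e.g. CH3): rotation produces indistinguishable copies."""
    subs = [n for n in g.neighbors(end) if n != other]
    if len(subs) < 3:
        return False
    els = {m.atoms[n].element for n in subs}
    return len(els) == 1 and all(g.degree[n] == 1 for n in subs)


def _is_amide_bond(m: Molecule, g: nx.Graph, i: int, j: int) -> bool:
    for n_idx, c_idx in ((i, j), (j, i)):
        if m.atoms[n_idx].element != "N" or m.atoms[c_idx].element != "C":
            continue
        for b in m.bonds:
            if b.order == 2 and c_idx in (b.i, b.j):
                o = b.j if b.i == c_idx else b.i
                if m.atoms[o].element == "O":
                    return True
    return False


def find_rotatable_bonds(m: Molecule) -> RotatableBondSet:
    """Classify bonds for torsion sampling.

    Ring bonds are never rotatable (anomeric configuration is stereochemistry,
    never sampled as a rotation); exocyclic glycosidic C-O bonds are rotatable
    (the phi/psi torsions), as are C-OH and exocyclic CH2OH bonds.  Bonds to
    monovalent atoms and locally symmetric rotors (CH3) are excluded because
    rotating them produces no distinguishable conformer.
    """
    g = m.graph()
    bridges = set()
    for u, v in nx.bridges(g):
        bridges.add((min(u, v), max(u, v)))
    rotatable = []
    reasons: dict[tuple[int, int], str] = {}
    for b in m.bonds:
        key = (min(b.i, b.j), max(b.i, b.j))
        if b.order != 1:
            reasons[key] = "order"
            continue
        if key not in bridges:  # an edge in a cycle is not a bridge
            reasons[key] = "ring"
            continue
        ai, aj = m.atoms[b.i], m.atoms[b.j]
        if ai.is_hydrogen or aj.is_hydrogen or g.degree[b.i] == 1 or g.degree[b.j] == 1:
            reasons[key] = "terminal"
            continue
        if _is_symmetric_rotor(m, g, b.i, b.j) or _is_symmetric_rotor(m, g, b.j, b.i):
            reasons[key] = "terminal"
            continue
        if _is_amide_bond(m, g, b.i, b.j):
            reasons[key] = "amide"
            continue
        code = "generic"
        if {ai.element, aj.element} == {"C", "O"}:
            o_idx = b.i if ai.element == "O" else b.j
            o_carbons = [n for n in g.neighbors(o_idx) if m.atoms[n].element == "C"]
            if len(o_carbons) == 2:
                code = "glycosidic-exocyclic"
        rotatable.append(key)
        reasons[key] = code
    return RotatableBondSet(rotatable=sorted(rotatable), reasons=reasons)
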