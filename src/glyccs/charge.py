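"""Charge-model enumeration: systematic [M - H]- / [M + H]+ candidates.

The protonation or deprotonation site of a gas-phase glycan ion is not
known a priori, so the workflow cycles over every titratable site of a
seed structure and emits one modified molecule per site.  Site classes are
perceived from local graph patterns:

=================  ====================================================
class              pattern
=================  ====================================================
hydroxyl_O         O bonded to one C and one H
carboxyl_O         O-H whose C neighbor carries a double-bonded O
carbonyl_O         O double-bonded to C, no H
ether_or_ring_O    O single-bonded to two C (ring or glycosidic)
amine_N            N with only single bonds, not adjacent to a carbonyl
amide_N            N single-bonded to a carbonyl C
=================  ====================================================

Negative mode deprotonates O-H / N-H sites; positive mode protonates
hydroxyl, carbonyl and ether/ring oxygens plus amine nitrogens.  Amide N
protonation is off by default (O-protonation of amides is preferred in the
gas phase) but can be enabled.  Multiply charged species, zwitterions and
adducts are out of scope: every model is singly charged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import networkx as nx
import numpy as np

from .molecule import Bond, Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "IonMode",
    "SiteClass",
    "TitratableSite",
    "ChargeModel",
    "find_titratable_sites",
    "enumerate_charge_models",
    "deduplicate_models",
]

# new-proton bond lengths, Å
OH_BOND_LENGTH = 0.96
NH_BOND_LENGTH = 1.01

# proton (H atom) mass bookkeeping uses the monoisotopic H mass; the
# electron mass is ignored throughout (documented in molecule.py)


class IonMode(str, Enum):
    neg = "neg"  # [M - H]-
    pos = "pos"  # [M + H]+


class SiteClass(str, Enum):
    hydroxyl_O = "hydroxyl_O"
    carboxyl_O = "carboxyl_O"
    carbonyl_O = "carbonyl_O"
    ether_or_ring_O = "ether_or_ring_O"
    amine_N = "amine_N"
    amide_N = "amide_N"


@dataclass(frozen=True)
class TitratableSite:
    atom_index: int
    site_class: SiteClass
    eligible_modes: frozenset[IonMode]


@dataclass
class ChargeModel:
    parent_label: str
    mode: IonMode
    site: TitratableSite
    molecule: Molecule
    enum_index: int  # 1-based enumeration order (I, II, ...)

    @property
    def enum_label(self) -> str:
        return _roman(self.enum_index)

    @property
    def label(self) -> str:
        sign = "-H" if self.mode is IonMode.neg else "+H"
        return f"{self.parent_label}[M{sign}]{self.enum_label}"


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
            (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def _classify_heteroatom(m: Molecule, g: nx.Graph, i: int) -> SiteClass | None:
    el = m.atoms[i].element
    nbrs = list(g.neighbors(i))
    h_nbrs = [n for n in nbrs if m.atoms[n].is_hydrogen]
    c_nbrs = [n for n in nbrs if m.atoms[n].element == "C"]
    orders = {(min(i, n), max(i, n)): g.edges[i, n]["order"] for n in nbrs}

    def carbonyl_carbon(c: int) -> bool:
        return any(
            g.edges[c, n]["order"] == 2 and m.atoms[n].element == "O"
            for n in g.neighbors(c)
            if n != i
        )

    if el == "O":
        if any(o == 2 for o in orders.values()):
            return SiteClass.carbonyl_O
        if len(h_nbrs) >= 1 and len(c_nbrs) == 1:
            return SiteClass.carboxyl_O if carbonyl_carbon(c_nbrs[0]) else SiteClass.hydroxyl_O
        if len(c_nbrs) == 2:
            return SiteClass.ether_or_ring_O
        return None
    if el == "N":
        if any(o != 1 for o in orders.values()):
            return None
        if any(carbonyl_carbon(c) for c in c_nbrs):
            return SiteClass.amide_N
        return SiteClass.amine_N
    return None


_DEPROTONATABLE = {
    SiteClass.hydroxyl_O,
    SiteClass.carboxyl_O,
    SiteClass.amine_N,
    SiteClass.amide_N,
}
_PROTONATABLE = {
    SiteClass.hydroxyl_O,
    SiteClass.carboxyl_O,
    SiteClass.carbonyl_O,
    SiteClass.ether_or_ring_O,
    SiteClass.amine_N,
}


def find_titratable_sites(
    m: Molecule,
    mode: IonMode | str,
    include_amide_protonation: bool = False,
) -> list[TitratableSite]:
    """All acidic/basic sites for the requested ion mode, ordered by atom index.

    Deprotonation (neg) requires at least one H on the site heteroatom;
    protonation (pos) requires a lone pair by valence count (all oxygen
    classes and amines qualify; already-charged atoms never do).
    """
    mode = IonMode(mode)
    g = m.graph()
    sites = []
    for i, a in enumerate(m.atoms):
        if a.element not in ("O", "N") or a.formal_charge != 0:
            continue
        cls = _classify_heteroatom(m, g, i)
        if cls is None:
            continue
        has_h = any(m.atoms[n].is_hydrogen for n in g.neighbors(i))
        modes = set()
        if cls in _DEPROTONATABLE and has_h:
            modes.add(IonMode.neg)
        protonatable = _PROTONATABLE | ({SiteClass.amide_N} if include_amide_protonation else set())
        if cls in protonatable:
            modes.add(IonMode.pos)
        if mode in modes:
            sites.append(TitratableSite(i, cls, frozenset(modes)))
    return sites


def _deprotonate(m: Molecule, site: TitratableSite) -> Molecule:
    g = m.graph()
    hs = sorted(n for n in g.neighbors(site.atom_index) if m.atoms[n].is_hydrogen)
    if not hs:
        raise RuntimeError(f"site {site.atom_index} has no removable H (contract violation)")
    if len(hs) > 1:
        logger.warning("site %d bears %d hydrogens; removing the first by index", site.atom_index, len(hs))
    h = hs[0]
    out = m.copy()
    out.atoms[site.atom_index].formal_charge = -1
    del out.atoms[h]
    remap = {old: (old if old < h else old - 1) for old in range(m.n_atoms) if old != h}
    out.bonds = [
        Bond(remap[b.i], remap[b.j], b.order) for b in m.bonds if h not in (b.i, b.j)
    ]
    out.stereo = {
        "tetrahedral": {remap[i]: d for i, d in m.stereo.get("tetrahedral", {}).items() if i != h},
        "double_bond": {
            (remap[i], remap[j]): d
            for (i, j), d in m.stereo.get("double_bond", {}).items()
            if h not in (i, j)
        },
    }
    return out


def _protonate(m: Molecule, site: TitratableSite) -> Molecule:
    """Place a new H at standard bond length along the lone-pair bisector
    (negative of the sum of unit vectors to existing bonded neighbors)."""
    out = m.copy()
    i = site.atom_index
    pos = out.atoms[i].position
    nbrs = m.neighbors(i)
    direction = np.zeros(3)
    for n in nbrs:
        v = m.atoms[n].position - pos
        direction -= v / np.linalg.norm(v)
    norm = np.linalg.norm(direction)
    if norm < 1e-8:  # linear/naked site: pick any perpendicular direction
        ref = m.atoms[nbrs[0]].position - pos if nbrs else np.array([1.0, 0.0, 0.0])
        direction = np.cross(ref, [0.0, 0.0, 1.0])
        if np.linalg.norm(direction) < 1e-8:
            direction = np.cross(ref, [0.0, 1.0, 0.0])
        norm = np.linalg.norm(direction)
    direction /= norm
    length = NH_BOND_LENGTH if out.atoms[i].element == "N" else OH_BOND_LENGTH
    from .molecule import Atom  # local import to avoid cycle at module load

    out.atoms[i].formal_charge = +1
    out.atoms.append(Atom("H", pos + length * direction))
    out.bonds = list(out.bonds) + [Bond(i, len(out.atoms) - 1, 1)]
    return out


def enumerate_charge_models(
    m: Molecule,
    mode: IonMode | str,
    include_amide_protonation: bool = False,
) -> list[ChargeModel]:
    """One singly-charged model per titratable site, seed geometry untouched.

    Deprotonation deletes the site's proton; protonation adds one at
    standard bond length.  Every model differs from the seed by exactly one
    hydrogen and carries net charge -1 (neg) or +1 (pos).
    """
    mode = IonMode(mode)
    sites = find_titratable_sites(m, mode, include_amide_protonation)
    if not sites:
        logger.warning("no titratable sites on %r for mode %s", m.label or "<unnamed>", mode.value)
        return []
    models = []
    for k, site in enumerate(sites, start=1):
        mol = _deprotonate(m, site) if mode is IonMode.neg else _protonate(m, site)
        mol.label = f"{m.label}_{mode.value}_{_roman(k)}"
        models.append(ChargeModel(m.label, mode, site, mol, k))
    return models


def deduplicate_models(models: list[ChargeModel]) -> list[ChargeModel]:
    """Merge models whose modified molecules are graph-isomorphic including
    the charge site (element + formal charge node attributes); the lowest
    enumeration index of each equivalence class is kept."""
    kept: list[ChargeModel] = []
    for model in sorted(models, key=lambda c: c.enum_index):
        g = model.molecule.graph()
        duplicate = False
        for other in kept:
            if nx.is_isomorphic(
                g,
                other.molecule.graph(),
                node_match=lambda a, b: a["element"] == b["element"]
                and a["formal_charge"] == b["formal_charge"],
            ):
                duplicate = True
                break
        if not duplicate:
            kept.append(model)
    return kept
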