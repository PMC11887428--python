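"""Deterministic toy-molecule generators for tests, examples and smoke runs.

Families range from a single sphere (analytic projection CCS) to a
synthetic disaccharide-like bicyclic ether carrying hydroxyl groups (at
least two titratable sites), which exercises every pipeline stage at a
size where the whole workflow runs in seconds.  All geometries are
reproducible for a given seed.

``from_smiles`` builds real carbohydrates (glucose, cellobiose,
melezitose, ...) through RDKit's distance-geometry embedding; it is a
fixture generator, not part of the structure-assignment workflow, which
starts from 3D files with explicit hydrogens.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .io import from_rdkit
from .molecule import Atom, Bond, Molecule, assign_stereo

__all__ = ["make_fixture", "from_smiles", "FIXTURE_FAMILIES", "SMILES"]

# a few carbohydrate connectivity strings used by tests and examples
SMILES = {
    "glucose": "OCC1OC(O)C(O)C(O)C1O",
    "cellobiose": "OCC1OC(OC2C(O)C(O)C(CO)OC2O)C(O)C(O)C1O",
    "melezitose": "OCC1OC(OC2(CO)OC(CO)C(O)C2OC3OC(CO)C(O)C(O)C3O)C(O)C(O)C1O",
    "sucrose": "OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O",
    "ethylene_glycol": "OCCO",
}

_FAMILY_SMILES = {
    "alkane": None,  # parametrized by n_carbons
    "ring": "C1CCCCC1",
    "diol": "OCCO",
    "disaccharide": "OC1CCCOC1OC1OCCCC1O",
}

FIXTURE_FAMILIES = ("sphere", "dumbbell", "alkane", "ring", "diol", "disaccharide")


def from_smiles(smiles: str, seed: int = 0, label: str = "", relax: bool = True) -> Molecule:
    """3D molecule with explicit hydrogens from a SMILES string.

    Distance-geometry embedding with a fixed random seed followed by an
    optional UFF clean-up; deterministic for a given (smiles, seed).
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise RuntimeError(f"3D embedding failed for {smiles!r}")
    if relax:
        AllChem.UFFOptimizeMolecule(rdmol, maxIters=2000)
    m = from_rdkit(rdmol, label=label or smiles)
    return m


def make_fixture(family: str, seed: int = 0, **params) -> Molecule:
    """Build a toy molecule from a named family.

    sphere
        one atom (``element``, default C); PA CCS is analytic.
    dumbbell
        two atoms at ``separation`` Å (default 2.0).
    alkane
        n-alkane with ``n_carbons`` (default 4).
    ring
        cyclohexane: rigid, zero rotatable bonds after symmetry rules.
    diol
        ethylene glycol: two symmetry-equivalent hydroxyls (dedup fixture).
    disaccharide
        two tetrahydropyran rings joined by an ether bridge, one hydroxyl
        on each ring: >= 2 titratable sites, a glycosidic-like torsion.
    """
    if family == "sphere":
        el = params.get("element", "C")
        return Molecule([Atom(el, np.zeros(3))], [], {}, label="sphere")
    if family == "dumbbell":
        el = params.get("element", "C")
        d = float(params.get("separation", 2.0))
        m = Molecule(
            [Atom(el, np.zeros(3)), Atom(el, np.array([d, 0.0, 0.0]))],
            [Bond(0, 1, 1)],
            {},
            label="dumbbell",
        )
        return m
    if family == "alkane":
        n = int(params.get("n_carbons", 4))
        return from_smiles("C" * n, seed=seed, label=f"alkane{n}")
    if family in _FAMILY_SMILES:
        return from_smiles(_FAMILY_SMILES[family], seed=seed, label=family)
    raise ValueError(f"unknown fixture family {family!r}; available: {FIXTURE_FAMILIES}")
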