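"""Structure file I/O: SDF/MOL V2000, PDB (ATOM/HETATM/CONECT), XYZ.

SDF and PDB records pass through RDKit; XYZ is read directly with an
extended comment line ``charge=<int>``.  Partial charges are serialized as
an SDF property block ``> <PARTIAL_CHARGES>`` (one float per atom line) and
as a JSON sidecar (``<file>.charges.json``) for XYZ.  Explicit hydrogens are
always preserved; nothing is ever added or removed on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

from .molecule import (
    Atom,
    Bond,
    Molecule,
    UnknownElementError,
    assign_stereo,
    perceive_bonds,
)

RDLogger.DisableLog("rdApp.*")

__all__ = ["read_structure", "write_structure", "StructureParseError", "to_rdkit", "from_rdkit"]

PARTIAL_CHARGE_PROP = "PARTIAL_CHARGES"

_BOND_ORDER_TO_RDKIT = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}
_RDKIT_TO_BOND_ORDER = {v: k for k, v in _BOND_ORDER_TO_RDKIT.items()}


class StructureParseError(ValueError):
    """Malformed structure record."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = path.suffix.lower().lstrip(".")
    if ext in ("sdf", "mol"):
        return "sdf"
    if ext in ("pdb", "xyz"):
        return ext
    raise ValueError(f"cannot infer structure format from {path.name!r}")


# -- RDKit conversion -----------------------------------------------------


def from_rdkit(rdmol: Chem.Mol, label: str = "") -> Molecule:
    """Convert an RDKit mol (with a conformer) to a :class:`Molecule`."""
    if rdmol.GetNumConformers() == 0:
        raise StructureParseError("RDKit molecule has no 3D coordinates")
    conf = rdmol.GetConformer()
    atoms = []
    for a in rdmol.GetAtoms():
        sym = a.GetSymbol()
        if a.GetAtomicNum() == 0:
            raise UnknownElementError(sym)
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(sym, np.array([p.x, p.y, p.z]), a.GetFormalCharge()))
    bonds = []
    for b in rdmol.GetBonds():
        order = _RDKIT_TO_BOND_ORDER.get(b.GetBondType(), 1)
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    name = label or (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "")
    m = Molecule(atoms, bonds, {}, name)
    if rdmol.HasProp(PARTIAL_CHARGE_PROP):
        q = [float(x) for x in rdmol.GetProp(PARTIAL_CHARGE_PROP).split()]
        m.set_partial_charges(q)
    m.stereo = assign_stereo(m)
    return m


def to_rdkit(m: Molecule) -> Chem.Mol:
    """Convert a :class:`Molecule` to an RDKit mol with one conformer.

    Hydrogens stay explicit (NoImplicit) so RDKit never invents protons on
    charged oxygens.
    """
    rw = Chem.RWMol()
    for a in m.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for b in m.bonds:
        rw.AddBond(b.i, b.j, _BOND_ORDER_TO_RDKIT.get(b.order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(m.n_atoms)
    for i, a in enumerate(m.atoms):
        conf.SetAtomPosition(i, Point3D(*a.position))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", m.label)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    return mol


# -- readers --------------------------------------------------------------


def _read_sdf(path: Path) -> Molecule:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    rdmol = next(iter(supplier), None)
    if rdmol is None:
        raise StructureParseError(f"{path}: malformed SDF/MOL record (first record failed to parse)")
    return from_rdkit(rdmol, label=Path(path).stem)


def _read_pdb(path: Path) -> Molecule:
    rdmol = Chem.MolFromPDBFile(str(path), sanitize=False, removeHs=False, proximityBonding=False)
    if rdmol is None:
        raise StructureParseError(f"{path}: malformed PDB record")
    # validate element symbols against the raw records so an unknown code
    # errors with its line number instead of being skipped
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            sym = line[76:78].strip() or line[12:16].strip()[:1]
            try:
                Atom(sym.capitalize() if len(sym) == 2 else sym, np.zeros(3))
            except UnknownElementError:
                raise StructureParseError(
                    f"{path}:{lineno}: unknown element code {sym!r}"
                ) from None
    m = from_rdkit(rdmol, label=Path(path).stem)
    if not m.bonds:  # no CONECT records: fall back to distance perception
        m = Molecule(m.atoms, perceive_bonds(m.atoms), {}, m.label)
        m.stereo = assign_stereo(m)
    return m


def _read_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise StructureParseError(f"{path}:1: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError(f"{path}:1: expected atom count") from None
    comment = lines[1]
    net_charge = 0
    for tok in comment.split():
        if tok.startswith("charge="):
            net_charge = int(tok.split("=", 1)[1])
    atoms = []
    for k, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise StructureParseError(f"{path}:{k}: malformed XYZ atom line")
        try:
            pos = np.array([float(x) for x in parts[1:4]])
        except ValueError:
            raise StructureParseError(f"{path}:{k}: non-numeric coordinate") from None
        atoms.append(Atom(parts[0], pos))
    if len(atoms) != n:
        raise StructureParseError(f"{path}: header promises {n} atoms, found {len(atoms)}")

    sidecar = path.with_suffix(path.suffix + ".charges.json")
    formal = None
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        if "partial_charges" in data:
            for a, q in zip(atoms, data["partial_charges"]):
                a.partial_charge = float(q)
        formal = data.get("formal_charges")
    if formal is not None:
        for a, fc in zip(atoms, formal):
            a.formal_charge = int(fc)
    if sum(a.formal_charge for a in atoms) != net_charge:
        if formal is not None:
            raise StructureParseError(
                f"{path}: sidecar formal charges sum to "
                f"{sum(a.formal_charge for a in atoms)}, header says charge={net_charge}"
            )
        if net_charge != 0:
            raise StructureParseError(
                f"{path}: charge={net_charge} requires a formal_charges sidecar "
                "(the charged site cannot be inferred from coordinates alone)"
            )
    m = Molecule(atoms, perceive_bonds(atoms), {}, path.stem)
    m.stereo = assign_stereo(m)
    return m


def read_structure(path, format: str | None = None) -> Molecule:
    """Read a structure file into a :class:`Molecule`.

    Bond orders come from the file when present (SDF, PDB CONECT); otherwise
    bonds are perceived from interatomic distances against covalent radii.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported format {fmt!r}")


# -- writers --------------------------------------------------------------


def _write_sdf(m: Molecule, path: Path, properties: dict | None) -> None:
    rdmol = to_rdkit(m)
    if np.any(m.partial_charges != 0):
        rdmol.SetProp(PARTIAL_CHARGE_PROP, "\n".join(f"{q:.6f}" for q in m.partial_charges))
    for k, v in (properties or {}).items():
        rdmol.SetProp(str(k), str(v))
    with Chem.SDWriter(str(path)) as w:
        w.SetKekulize(False)
        w.write(rdmol)


def _write_pdb(m: Molecule, path: Path) -> None:
    rdmol = to_rdkit(m)
    Chem.MolToPDBFile(rdmol, str(path))


def _write_xyz(m: Molecule, path: Path) -> None:
    lines = [str(m.n_atoms), f"charge={m.net_charge} {m.label}".strip()]
    for a in m.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
    path.write_text("\n".join(lines) + "\n")
    if np.any(m.partial_charges != 0) or m.net_charge != 0:
        sidecar = path.with_suffix(path.suffix + ".charges.json")
        sidecar.write_text(
            json.dumps(
                {
                    "partial_charges": [round(float(q), 6) for q in m.partial_charges],
                    "formal_charges": [a.formal_charge for a in m.atoms],
                }
            )
        )


def write_structure(m: Molecule, path, format: str | None = None, properties: dict | None = None) -> None:
    """Write a :class:`Molecule` to SDF/MOL, PDB, or XYZ."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sdf":
        _write_sdf(m, path, properties)
    elif fmt == "pdb":
        _write_pdb(m, path)
    elif fmt == "xyz":
        _write_xyz(m, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
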