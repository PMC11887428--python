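"""Surrogate energy backend: relaxation, ranking, and partial charges.

The reference workflow scores charge models and conformers with DFT
electronic energies; only *relative* energies (RE = E_i - E_min) ever enter
the selection rules, so any backend that provides a consistent energy
scale, a relaxed geometry and per-atom partial charges satisfies the
contract.  The built-in surrogate uses the UFF force field (via RDKit) for
energies and relaxation, and
Gasteiger-Marsili electronegativity equalization for partial charges.  An adapter for an external engine can be
registered through :func:`register_backend`; the file contract is simply
"return an :class:`EnergyResult`".

Energy zero-points are backend-defined and meaningless on their own: the
retention window is applied to RE only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import AllChem

from .charge import ChargeModel
from .io import to_rdkit
from .molecule import Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyResult",
    "CandidateSet",
    "BackendConfig",
    "evaluate",
    "rank_and_filter",
    "gasteiger_charges",
    "uff_energy",
    "uff_minimize",
    "register_backend",
]

# RE retention window for charge-state candidates, kcal/mol, boundary
# inclusive ("within 10 kcal/mol" of the global minimum).
DEFAULT_WINDOW_KCAL = 10.0

@dataclass
class BackendConfig:
    name: str = "surrogate"
    window_kcal: float = DEFAULT_WINDOW_KCAL
    max_steps: int = 2000
    grad_tol: float = 1e-4  # kcal/mol/Angstrom force tolerance for relaxation
    charge_scheme: str = "gasteiger"


@dataclass
class EnergyResult:
    energy: float  # kcal/mol on the backend scale
    coords: np.ndarray  # relaxed geometry, (N, 3) Angstrom
    partial_charges: np.ndarray  # per-atom, e
    backend: str
    converged: bool


@dataclass
class CandidateSet:
    """Charge models ranked by relative energy with retention flags."""

    models: list[ChargeModel]
    results: list[EnergyResult]
    relative_energies: list[float] = field(default_factory=list)
    retained: list[bool] = field(default_factory=list)
    window_kcal: float = DEFAULT_WINDOW_KCAL

    @property
    def e_min(self) -> float:
        return min(r.energy for r in self.results)

    @property
    def retained_models(self) -> list[ChargeModel]:
        return [m for m, keep in zip(self.models, self.retained) if keep]


def gasteiger_charges(m: Molecule) -> np.ndarray:
    """Partial charges by partial equalization of orbital electronegativity
    (Gasteiger-Marsili, via RDKit).

    Charges sum to the molecular net charge exactly (the iteration only
    transfers charge between bonded atoms, starting from the formal
    charges), are deterministic, and behave sensibly for the deprotonated
    and protonated oxygen sites this workflow creates.  They are a
    classical stand-in for the QM (Mulliken) charges of the reference
    workflow and are labeled as such in all outputs.
    """
    if m.n_atoms == 0:
        return np.zeros(0)
    rdmol = to_rdkit(m)
    AllChem.ComputeGasteigerCharges(rdmol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in rdmol.GetAtoms()])
    if not np.all(np.isfinite(q)):
        raise RuntimeError(f"Gasteiger charges undefined for {m.label!r}")
    return q


def uff_energy(m: Molecule) -> float:
    """Single-point UFF energy, kcal/mol."""
    rdmol = to_rdkit(m)
    ff = AllChem.UFFGetMoleculeForceField(rdmol)
    return float(ff.CalcEnergy())


def uff_minimize(m: Molecule, max_steps: int = 2000, grad_tol: float = 1e-4) -> tuple[float, np.ndarray, bool]:
    """Relax a geometry with UFF; returns (energy, coords, converged)."""
    rdmol = to_rdkit(m)
    ff = AllChem.UFFGetMoleculeForceField(rdmol)
    rc = ff.Minimize(maxIts=max_steps, forceTol=grad_tol)
    coords = np.array(rdmol.GetConformer().GetPositions())
    # fresh single-point at the final geometry: the minimizer's own energy
    # report can lag its last write-back by ~1e-6 kcal/mol
    energy = float(AllChem.UFFGetMoleculeForceField(rdmol).CalcEnergy())
    return energy, coords, rc == 0


def _surrogate_evaluate(molecule: Molecule, config: BackendConfig) -> EnergyResult:
    try:
        energy, coords, converged = uff_minimize(molecule, config.max_steps, config.grad_tol)
    except Exception as exc:  # typing failure, pathological geometry, ...
        logger.warning("surrogate evaluation failed for %r: %s", molecule.label, exc)
        return EnergyResult(np.nan, molecule.coords, np.zeros(molecule.n_atoms), "surrogate-uff", False)
    relaxed = molecule.with_coords(coords)
    charges = gasteiger_charges(relaxed)
    return EnergyResult(energy, coords, charges, "surrogate-uff", converged)


_BACKENDS = {"surrogate": _surrogate_evaluate}


def register_backend(name: str, fn) -> None:
    """Register an external energy engine adapter.

    ``fn(molecule, config) -> EnergyResult``.  Adapters for external QM
    engines should write their own input deck, run out-of-process, and parse
    energy (kcal/mol), relaxed coordinates and per-atom charges back.
    """
    _BACKENDS[name] = fn


def evaluate(model: ChargeModel | Molecule, config: BackendConfig | None = None) -> EnergyResult:
    """Relax one charge model (or bare molecule) and return its energy,
    relaxed geometry and partial charges.  Deterministic for a fixed input."""
    config = config or BackendConfig()
    molecule = model.molecule if isinstance(model, ChargeModel) else model
    backend = _BACKENDS.get(config.name)
    if backend is None:
        raise ValueError(f"unknown energy backend {config.name!r} (have {sorted(_BACKENDS)})")
    return backend(molecule, config)


def rank_and_filter(
    pairs: list[tuple[ChargeModel, EnergyResult]],
    window_kcal: float = DEFAULT_WINDOW_KCAL,
) -> CandidateSet:
    """Rank charge models by relative energy and retain those within the
    window (inclusive) of the converged global minimum.

    Non-converged results are excluded from ranking with a warning; zero
    converged results is a hard error.  Output is sorted ascending by RE
    with ties broken by enumeration index, so the global minimum is first.
    """
    converged = [(m, r) for m, r in pairs if r.converged and np.isfinite(r.energy)]
    dropped = len(pairs) - len(converged)
    if dropped:
        logger.warning("excluding %d non-converged charge model(s) from ranking", dropped)
    if not converged:
        raise RuntimeError("no converged energy results: cannot rank charge models")
    e_min = min(r.energy for _, r in converged)
    ordered = sorted(converged, key=lambda mr: (mr[1].energy - e_min, mr[0].enum_index))
    models = [m for m, _ in ordered]
    results = [r for _, r in ordered]
    res = [r.energy - e_min for r in results]
    retained = [re <= window_kcal for re in res]
    return CandidateSet(models, results, res, retained, window_kcal)
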