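"""Conformer ensemble generation and reduction to representative centers.

Conformers are produced by stochastic torsion sampling on the rotatable
bonds (uniform over a 60 degree grid with +/-15 degree jitter, covering the
sp3 rotamer wells without grid artifacts) followed by a short surrogate
minimization for clash relief.  Duplicates are removed at 0.1 Å heavy-atom
RMSD after optimal superposition.  Ensembles larger than 50 conformers are
clustered on the pairwise RMSD matrix with a deterministic graph community
method and each cluster contributes its lowest-energy member as a
representative center; smaller ensembles pass through unclustered.  The
global-minimum conformer is a center by construction (it is the energy
minimum of whichever cluster contains it).

This reproduces the *behavioral contract* of the reference workflow's
external generator and clusterer (target count, the >50 rule,
representative centers), not their internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .charge import ChargeModel
from .energy import BackendConfig, evaluate
from .molecule import Molecule, find_rotatable_bonds, stereo_parities

logger = logging.getLogger(__name__)

__all__ = [
    "Conformer",
    "ConformerEnsemble",
    "ClusterSummary",
    "generate_conformers",
    "cluster_ensemble",
    "align_rmsd",
    "kabsch_rmsd",
    "set_torsion",
]

TORSION_GRID_DEG = 60.0
TORSION_JITTER_DEG = 15.0
DUPLICATE_RMSD = 0.1  # Å, heavy atoms
CLUSTER_THRESHOLD_COUNT = 50
# Community-detection resolution, frozen against a calibration fixture of
# three synthetic conformer bundles that must yield exactly three clusters.
CLUSTER_RESOLUTION = 1.0


@dataclass
class Conformer:
    coords: np.ndarray
    energy: float = np.nan
    relative_energy: float = np.nan
    cluster: int = -1
    is_center: bool = False


@dataclass
class ConformerEnsemble:
    model: ChargeModel
    conformers: list[Conformer]
    target: int
    seed: int

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])

    def score_relative_energies(self) -> None:
        e = self.energies
        e_min = np.nanmin(e)
        for c in self.conformers:
            c.relative_energy = c.energy - e_min

    @property
    def centers(self) -> list[Conformer]:
        return [c for c in self.conformers if c.is_center]


@dataclass
class ClusterSummary:
    n_clusters: int
    center_indices: list[int]
    rmsd_stats: dict = field(default_factory=dict)
    method: str = "greedy-modularity"


# -- RMSD -----------------------------------------------------------------


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD of two conformations over rigid superposition (SVD)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt((diff**2).sum() / len(a)))


def align_rmsd(a: np.ndarray, b: np.ndarray, heavy_only: bool = True, elements: list[str] | None = None) -> float:
    """RMSD after optimal rigid superposition; symmetric in its arguments.

    With ``heavy_only`` an element list must be supplied so hydrogens can be
    masked out (hydrogen positions are noise after minimization).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if heavy_only:
        if elements is None:
            raise ValueError("heavy_only RMSD requires the element list")
        mask = np.array([el != "H" for el in elements])
        a, b = a[mask], b[mask]
    return kabsch_rmsd(a, b)


# -- torsion manipulation -------------------------------------------------


def _subtree(g: nx.Graph, root: int, blocked: int) -> set[int]:
    h = g.copy()
    h.remove_edge(root, blocked)
    return nx.node_connected_component(h, root)


def set_torsion(m: Molecule, bond: tuple[int, int], angle_rad: float) -> None:
    """Set the dihedral about an acyclic bond to an absolute value (radians),
    rotating the smaller side.  Reference atoms are the lowest-index
    neighbors on each side, giving a reproducible torsion definition."""
    i, j = bond
    g = m.graph()
    side_j = _subtree(g, j, i)
    side_i = set(g.nodes) - side_j
    if len(side_j) > len(side_i):
        i, j = j, i
        side_j = side_i
    ref_i = min(n for n in g.neighbors(i) if n != j)
    ref_j = min(n for n in g.neighbors(j) if n != i)
    coords = m.coords
    b0 = coords[i] - coords[ref_i]
    b1 = coords[j] - coords[i]
    b2 = coords[ref_j] - coords[j]
    b1u = b1 / np.linalg.norm(b1)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    current = np.arctan2(np.dot(np.cross(n1, b1u), n2), np.dot(n1, n2))
    delta = angle_rad - current
    axis = b1u
    pivot = coords[j]
    rot = _rotation_matrix(axis, delta)
    moving = sorted(side_j - {j})
    coords[moving] = (coords[moving] - pivot) @ rot.T + pivot
    coords[j] = pivot
    m.set_coords(coords)


def _rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.cos(theta / 2.0)
    b, c, d = -axis * np.sin(theta / 2.0)
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
            [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
            [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
        ]
    )


# -- generation -----------------------------------------------------------


def generate_conformers(
    model: ChargeModel,
    target: int = 1000,
    seed: int = 0,
    backend: BackendConfig | None = None,
    relax_steps: int = 200,
    max_attempts: int | None = None,
) -> ConformerEnsemble:
    """Stochastic torsion sampling followed by clash-relief minimization.

    Produces at most ``target`` distinct conformers; systems with low
    degrees of freedom simply yield fewer (a molecule with zero rotatable
    bonds yields a single-conformer ensemble — logged, not an error).
    Stereo descriptors are asserted unchanged on every surviving conformer.
    """
    molecule = model.molecule if isinstance(model, ChargeModel) else model
    backend = backend or BackendConfig()
    rng = np.random.default_rng(seed)
    rot = find_rotatable_bonds(molecule).rotatable
    parent_parity = stereo_parities(molecule)
    elements = molecule.elements

    def relax(mol: Molecule) -> Conformer:
        res = evaluate(
            mol, BackendConfig(name=backend.name, max_steps=relax_steps, grad_tol=backend.grad_tol)
        )
        return Conformer(res.coords, res.energy)

    if not rot:
        logger.info("%r has no rotatable bonds: single-conformer ensemble", molecule.label)
        ens = ConformerEnsemble(model, [relax(molecule.copy())], target, seed)
        ens.score_relative_energies()
        return ens

    kept: list[Conformer] = []
    kept_rg: list[float] = []
    heavy = np.array([el != "H" for el in elements])
    grid = np.arange(0.0, 360.0, TORSION_GRID_DEG)
    attempts = 0
    budget = max_attempts if max_attempts is not None else max(2 * target, 20)
    while len(kept) < target and attempts < budget:
        attempts += 1
        trial = molecule.copy()
        for bond in rot:
            angle = rng.choice(grid) + rng.uniform(-TORSION_JITTER_DEG, TORSION_JITTER_DEG)
            set_torsion(trial, bond, np.deg2rad(angle))
        conf = relax(trial)
        if not np.isfinite(conf.energy):
            continue
        if stereo_parities(molecule.with_coords(conf.coords)) != parent_parity:
            logger.warning("discarding conformer with inverted stereocenter")
            continue
        hc = conf.coords[heavy]
        rg = float(np.sqrt(((hc - hc.mean(axis=0)) ** 2).sum(axis=1).mean()))
        duplicate = False
        for other, org in zip(kept, kept_rg):
            if abs(rg - org) > 0.05:
                continue
            if kabsch_rmsd(hc, other.coords[heavy]) < DUPLICATE_RMSD:
                duplicate = True
                break
        if not duplicate:
            kept.append(conf)
            kept_rg.append(rg)
    ens = ConformerEnsemble(model, kept, target, seed)
    ens.score_relative_energies()
    return ens


# -- clustering -----------------------------------------------------------


def cluster_ensemble(
    ens: ConformerEnsemble,
    threshold_count: int = CLUSTER_THRESHOLD_COUNT,
    resolution: float = CLUSTER_RESOLUTION,
) -> ClusterSummary:
    """Reduce an ensemble to representative centers.

    Ensembles of ``threshold_count`` or fewer conformers pass through with
    every conformer its own center.  Larger ensembles are partitioned by
    greedy modularity maximization on an affinity graph built from the
    aligned heavy-atom RMSD matrix (affinity = exp(-rmsd^2 / 2 sigma^2),
    sigma = median off-diagonal RMSD); each cluster's energy minimum
    becomes its center.
    """
    n = len(ens.conformers)
    molecule = ens.model.molecule if isinstance(ens.model, ChargeModel) else ens.model
    heavy = np.array([el != "H" for el in molecule.elements])
    if n <= threshold_count:
        for k, c in enumerate(ens.conformers):
            c.cluster = k
            c.is_center = True
        return ClusterSummary(n, list(range(n)), {"pass_through": True}, method="pass-through")

    coords = [c.coords[heavy] for c in ens.conformers]
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = kabsch_rmsd(coords[i], coords[j])
    off = rmsd[np.triu_indices(n, 1)]
    sigma = max(float(np.median(off)), 1e-6)
    affinity = np.exp(-(rmsd**2) / (2.0 * sigma**2))

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(affinity[i, j]))
    communities = nx.community.greedy_modularity_communities(
        g, weight="weight", resolution=resolution
    )
    energies = ens.energies
    centers = []
    for label, comm in enumerate(sorted(communities, key=min)):
        members = sorted(comm)
        for i in members:
            ens.conformers[i].cluster = label
            ens.conformers[i].is_center = False
        center = min(members, key=lambda i: (energies[i], i))
        ens.conformers[center].is_center = True
        centers.append(center)
    stats = {
        "min": float(off.min()),
        "median": sigma,
        "max": float(off.max()),
    }
    return ClusterSummary(len(communities), sorted(centers), stats)
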