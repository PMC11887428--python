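"""Conformer generation, RMSD alignment, and cluster reduction."""

import numpy as np
import pytest

from glyccs import fixtures
from glyccs.charge import enumerate_charge_models
from glyccs.conformers import (
    Conformer,
    ConformerEnsemble,
    align_rmsd,
    cluster_ensemble,
    generate_conformers,
    kabsch_rmsd,
)
from glyccs.molecule import Atom, Bond, Molecule, stereo_parities


class TestAlignRMSD:
    def test_identical_is_zero(self, glucose):
        assert align_rmsd(glucose.coords, glucose.coords, elements=glucose.elements) < 1e-9

    def test_rigid_motion_is_zero(self, glucose):
        from scipy.spatial.transform import Rotation

        moved = Rotation.from_euler("xyz", [0.3, 0.9, -1.4]).apply(glucose.coords) + [2, -7, 1]
        assert align_rmsd(glucose.coords, moved, elements=glucose.elements) < 1e-6

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)

    def test_four_point_toy_matches_rotation_grid_oracle(self):
        """Brute-force search over a dense rotation grid must agree with the
        closed-form Kabsch solution on a printed 4-point configuration."""
        a = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, 1.0]])
        b = np.array([[0.1, 0.0, 0.0], [1.4, 0.3, 0.0], [-0.2, 1.9, 0.4], [0.0, -0.1, 1.1]])
        ac, bc = a - a.mean(0), b - b.mean(0)
        from scipy.spatial.transform import Rotation

        best = np.inf
        n = 40
        for alpha in np.linspace(0, 2 * np.pi, n, endpoint=False):
            for beta in np.linspace(0, np.pi, n // 2):
                for gamma in np.linspace(0, 2 * np.pi, n, endpoint=False):
                    rot = Rotation.from_euler("zyz", [alpha, beta, gamma]).as_matrix()
                    r = np.sqrt((((ac @ rot.T) - bc) ** 2).sum() / 4)
                    best = min(best, r)
        closed_form = kabsch_rmsd(a, b)
        assert closed_form <= best + 1e-12  # the SVD solution is optimal
        assert best - closed_form < 5e-3  # grid resolution bound

    def test_mismatched_sizes_error(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestGeneration:
    def test_rigid_ring_yields_single_conformer(self):
        ring = fixtures.make_fixture("ring", seed=4)
        ens = generate_conformers(ring, target=1000, seed=0)
        assert len(ens.conformers) == 1
        assert ens.conformers[0].relative_energy == 0.0

    def test_butane_collapses_to_rotamer_wells(self, butane):
        # the C2-C3 torsion profile has three minima (anti, gauche+/-);
        # minimization + heavy-atom dedup can keep at most three
        ens = generate_conformers(butane, target=1000, seed=1, max_attempts=60)
        assert 1 <= len(ens.conformers) <= 3

    def test_fixed_seed_reproducible(self, glucose):
        model = enumerate_charge_models(glucose, "neg")[0]
        a = generate_conformers(model, target=10, seed=123)
        b = generate_conformers(model, target=10, seed=123)
        assert len(a.conformers) == len(b.conformers)
        for x, y in zip(a.conformers, b.conformers):
            assert np.array_equal(x.coords, y.coords) and x.energy == y.energy

    def test_stereo_preserved_and_re_zeroed(self, glucose):
        model = enumerate_charge_models(glucose, "neg")[1]
        ens = generate_conformers(model, target=10, seed=7)
        parent = stereo_parities(model.molecule)
        for c in ens.conformers:
            assert stereo_parities(model.molecule.with_coords(c.coords)) == parent
        re = np.array([c.relative_energy for c in ens.conformers])
        assert re.min() == 0.0 and (re >= 0).all()
        assert (re == 0.0).sum() == 1 or len(ens.conformers) == 1


def _toy_ensemble(bundles, noise, seed=42):
    """Synthetic ensemble: random base shapes, each perturbed into a tight
    bundle, with energies increasing across bundles."""
    rng = np.random.default_rng(seed)
    mol = Molecule(
        [Atom("C", p) for p in rng.normal(size=(5, 3)) * 3.0],
        [Bond(i, i + 1) for i in range(4)],
    )
    confs = []
    for k, n in enumerate(bundles):
        base = rng.normal(size=(5, 3)) * 3.0
        for _ in range(n):
            confs.append(Conformer(base + rng.normal(0, noise, base.shape), 5.0 * k + rng.uniform(0, 1)))
    ens = ConformerEnsemble(mol, confs, sum(bundles), seed)
    ens.score_relative_energies()
    return ens


class TestClustering:
    def test_small_ensemble_passes_through(self):
        for n in (40, 50):  # the >50 rule is exclusive at the boundary
            ens = _toy_ensemble([n], noise=0.3)
            summary = cluster_ensemble(ens)
            assert summary.method == "pass-through"
            assert summary.n_clusters == n
            assert all(c.is_center for c in ens.conformers)

    def test_two_tight_bundles_give_two_clusters(self):
        ens = _toy_ensemble([30, 30], noise=0.05)
        summary = cluster_ensemble(ens)
        assert summary.n_clusters == 2
        for label in range(2):
            members = [i for i, c in enumerate(ens.conformers) if c.cluster == label]
            centers = [i for i in members if ens.conformers[i].is_center]
            emin = min(members, key=lambda i: ens.conformers[i].energy)
            assert centers == [emin]

    def test_three_bundle_calibration(self):
        assert cluster_ensemble(_toy_ensemble([30, 30, 30], noise=0.02)).n_clusters == 3

    def test_partition_invariant_under_permutation(self):
        ens = _toy_ensemble([30, 30], noise=0.05)
        cluster_ensemble(ens)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(ens.conformers))
        shuffled = ConformerEnsemble(
            ens.model,
            [Conformer(ens.conformers[i].coords.copy(), ens.conformers[i].energy) for i in perm],
            ens.target,
            ens.seed,
        )
        shuffled.score_relative_energies()
        cluster_ensemble(shuffled)

        def blocks(e, index_map):
            from collections import defaultdict

            d = defaultdict(set)
            for i, c in enumerate(e.conformers):
                d[c.cluster].add(index_map(i))
            return {frozenset(v) for v in d.values()}

        assert blocks(ens, lambda i: i) == blocks(shuffled, lambda i: int(perm[i]))

    def test_global_minimum_is_always_a_center(self):
        ens = _toy_ensemble([40, 40], noise=0.08)
        cluster_ensemble(ens)
        gmin = int(np.argmin(ens.energies))
        assert ens.conformers[gmin].is_center
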