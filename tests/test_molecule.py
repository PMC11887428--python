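"""Molecular data model: masses, bond perception, stereo, rotatable bonds."""

import numpy as np
import pytest

from glyccs import fixtures
from glyccs.molecule import (
    Atom,
    Bond,
    Molecule,
    UnknownElementError,
    assign_stereo,
    find_rotatable_bonds,
    monoisotopic_mass,
    perceive_bonds,
    stereo_parities,
)


def water():
    return Molecule(
        [
            Atom("O", [0.0, 0.0, 0.0]),
            Atom("H", [0.96, 0.0, 0.0]),
            Atom("H", [-0.24, 0.93, 0.0]),
        ],
        [Bond(0, 1), Bond(0, 2)],
    )


class TestMonoisotopicMass:
    # expected values frozen from the principal-isotope mass table:
    # H 1.0078250319, C 12, O 15.9949146221
    def test_water(self):
        assert monoisotopic_mass(water()) == pytest.approx(18.0106, abs=1e-4)

    def test_glucose(self, glucose):
        assert monoisotopic_mass(glucose) == pytest.approx(180.0634, abs=1e-4)

    def test_empty_molecule_is_zero(self):
        assert monoisotopic_mass(Molecule([], [])) == 0.0

    def test_additive_over_disconnected_components(self, glucose):
        w = water()
        combined = Molecule(
            glucose.atoms + [a.copy() for a in w.atoms],
            glucose.bonds + [Bond(b.i + glucose.n_atoms, b.j + glucose.n_atoms) for b in w.bonds],
        )
        assert monoisotopic_mass(combined) == pytest.approx(
            monoisotopic_mass(glucose) + monoisotopic_mass(w), abs=1e-9
        )


class TestValidation:
    def test_unknown_element_rejected(self):
        with pytest.raises(UnknownElementError, match="Xx"):
            Atom("Xx", [0.0, 0.0, 0.0])

    def test_self_loop_bond_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            Molecule([Atom("C", [0, 0, 0])], [Bond(0, 0)])

    def test_nonfinite_position_rejected(self):
        with pytest.raises(ValueError):
            Atom("C", [np.nan, 0.0, 0.0])


class TestBondPerception:
    def test_water_distances(self):
        atoms = water().atoms
        assert sorted((b.i, b.j) for b in perceive_bonds(atoms)) == [(0, 1), (0, 2)]

    def test_far_atoms_not_bonded(self):
        atoms = [Atom("C", [0, 0, 0]), Atom("C", [5.0, 0, 0])]
        assert perceive_bonds(atoms) == []

    def test_glucose_connectivity_recovered(self, glucose):
        # distance perception on a relaxed sugar recovers the real bond graph
        perceived = {(b.i, b.j) for b in perceive_bonds(glucose.atoms)}
        actual = {(min(b.i, b.j), max(b.i, b.j)) for b in glucose.bonds}
        assert perceived == actual


class TestRotatableBonds:
    def test_ethane_has_none(self, ethane):
        assert find_rotatable_bonds(ethane).n_rotatable == 0

    def test_butane_has_central_bond_only(self, butane):
        rbs = find_rotatable_bonds(butane)
        assert rbs.n_rotatable == 1
        (i, j) = rbs.rotatable[0]
        # the one rotatable bond is carbon-carbon with both carbons bonded
        # to another carbon (the C2-C3 bond)
        g = butane.graph()
        for end in (i, j):
            assert butane.atoms[end].element == "C"
            heavy_nbrs = [n for n in g.neighbors(end) if not butane.atoms[n].is_hydrogen]
            assert len(heavy_nbrs) == 2

    def test_cellobiose_matches_graph_oracle(self, cellobiose):
        """Every acyclic single bond between heavy atoms is rotatable unless
        an endpoint is a symmetric rotor; enumerate them independently."""
        import networkx as nx

        g = cellobiose.graph()
        bridges = {tuple(sorted(e)) for e in nx.bridges(g)}
        expected = set()
        for b in cellobiose.bonds:
            key = tuple(sorted((b.i, b.j)))
            if b.order != 1 or key not in bridges:
                continue
            ai, aj = cellobiose.atoms[b.i], cellobiose.atoms[b.j]
            if ai.is_hydrogen or aj.is_hydrogen:
                continue
            if g.degree[b.i] == 1 or g.degree[b.j] == 1:
                continue
            sym = False
            for end, other in ((b.i, b.j), (b.j, b.i)):
                subs = [n for n in g.neighbors(end) if n != other]
                if (
                    len(subs) >= 3
                    and len({cellobiose.atoms[n].element for n in subs}) == 1
                    and all(g.degree[n] == 1 for n in subs)
                ):
                    sym = True
            if not sym:
                expected.add(key)
        rbs = find_rotatable_bonds(cellobiose)
        assert set(rbs.rotatable) == expected
        # cellobiose: 8 C-OH + 2 exocyclic CH2OH + 2 glycosidic C-O
        assert rbs.n_rotatable == 12
        assert sum(1 for c in rbs.reasons.values() if c == "glycosidic-exocyclic") == 2

    def test_ring_bonds_never_rotatable(self, glucose):
        rbs = find_rotatable_bonds(glucose)
        ring_keys = {k for k, v in rbs.reasons.items() if v == "ring"}
        assert len(ring_keys) == 6  # the pyranose ring
        assert not ring_keys & set(rbs.rotatable)

    def test_invariant_under_atom_reordering(self, butane):
        rng = np.random.default_rng(0)
        perm = rng.permutation(butane.n_atoms)
        inv = np.argsort(perm)
        reordered = Molecule(
            [butane.atoms[p].copy() for p in perm],
            [Bond(int(inv[b.i]), int(inv[b.j]), b.order) for b in butane.bonds],
        )
        orig = {tuple(sorted((perm[i], perm[j]))) for i, j in find_rotatable_bonds(reordered).rotatable}
        assert orig == set(find_rotatable_bonds(butane).rotatable)


class TestStereo:
    def test_glucose_has_five_stereocenters(self, glucose):
        stereo = assign_stereo(glucose)
        assert len(stereo["tetrahedral"]) == 5

    def test_labels_stable_under_rigid_motion(self, glucose):
        from scipy.spatial.transform import Rotation

        rotated = glucose.with_coords(
            Rotation.from_euler("xyz", [0.7, -0.2, 1.9]).apply(glucose.coords) + [4.0, -1.0, 2.0]
        )
        assert assign_stereo(rotated) == assign_stereo(glucose)

    def test_mirror_image_flips_every_parity(self, glucose):
        mirrored = glucose.with_coords(glucose.coords * np.array([-1.0, 1.0, 1.0]))
        p0 = stereo_parities(glucose)
        p1 = stereo_parities(mirrored)
        assert p0.keys() == p1.keys() and len(p0) > 0
        assert all(p1[i] == -p0[i] for i in p0)
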