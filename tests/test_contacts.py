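"""Interface contacts at the 5 Å side-chain threshold and helix-face triples."""

import numpy as np
import pytest

import helixsurf as hs
from helixsurf.contacts import ContactMap, ContactPair, ContactParams, ResidueRef
from helixsurf.structure import StructureError


def single_residue(chain, resnum, resname, cb_xyz, extra=()):
    """One residue with N/CA backbone and a CB side chain at cb_xyz."""
    cb = np.asarray(cb_xyz, float)
    atoms = [
        hs.Atom(1, "N", "N", resname, resnum, chain, cb + [0, 0, 3.0], radius=1.55),
        hs.Atom(2, "CA", "C", resname, resnum, chain, cb + [0, 0, 1.5], radius=1.7),
        hs.Atom(3, "CB", "C", resname, resnum, chain, cb, radius=1.7),
    ]
    for i, (name, pos) in enumerate(extra):
        atoms.append(hs.Atom(4 + i, name, "C", resname, resnum, chain, np.asarray(pos, float), radius=1.7))
    return hs.Structure(atoms)


def contact_map_for(numbers, chain="P"):
    """ContactMap whose peptide residues carry the given numbers."""
    dummy_receptor = ResidueRef("A", 1, "", "LEU")
    pairs = [
        ContactPair(dummy_receptor, ResidueRef(chain, n, "", "ALA"), 4.0)
        for n in numbers
    ]
    return ContactMap(pairs)


class TestContactResidues:
    def test_pair_just_below_cutoff(self):
        a = single_residue("A", 1, "LEU", [0, 0, 0])
        b = single_residue("B", 1, "TRP", [4.9, 0, 0])
        cm = hs.contact_residues(a, b)
        assert len(cm.pairs) == 1
        assert cm.pairs[0].min_distance == pytest.approx(4.9)

    def test_pair_just_above_cutoff(self):
        a = single_residue("A", 1, "LEU", [0, 0, 0])
        b = single_residue("B", 1, "TRP", [5.1, 0, 0])
        assert hs.contact_residues(a, b).pairs == []

    def test_boundary_is_inclusive(self):
        a = single_residue("A", 1, "LEU", [0, 0, 0])
        b = single_residue("B", 1, "TRP", [5.0, 0, 0])
        assert len(hs.contact_residues(a, b).pairs) == 1

    def test_backbone_proximity_does_not_count_when_sidechain_only(self):
        # N atoms 2 Å apart but CB atoms far: no side-chain contact
        a = single_residue("A", 1, "LEU", [0, 0, 0])
        b = single_residue("B", 1, "TRP", [8.0, 0, 0])
        b_shifted = b.transformed(translation=np.array([0.0, 0.0, 0.0]))
        assert hs.contact_residues(a, b_shifted).pairs == []
        both = hs.contact_residues(
            a, b_shifted, ContactParams(cutoff=9.0, sidechain_only=False)
        )
        assert len(both.pairs) == 1

    def test_glycine_contacts_through_ca(self):
        gly = hs.Structure([
            hs.Atom(1, "N", "N", "GLY", 1, "A", np.array([0.0, 0, 3.0]), radius=1.55),
            hs.Atom(2, "CA", "C", "GLY", 1, "A", np.array([0.0, 0, 0.0]), radius=1.7),
        ])
        trp = single_residue("B", 9, "TRP", [4.0, 0, 0])
        cm = hs.contact_residues(gly, trp)
        assert [p.receptor.name for p in cm.pairs] == ["GLY"]

    def test_empty_partner_rejected(self, groove):
        receptor, peptide, _ = groove
        with pytest.raises(StructureError):
            hs.contact_residues(receptor, hs.Structure([]))

    def test_symmetry_under_swap(self, groove):
        receptor, peptide, _ = groove
        fwd = hs.contact_residues(receptor, peptide)
        rev = hs.contact_residues(peptide, receptor)
        assert fwd.pair_keys == {(b, a) for a, b in rev.pair_keys}

    def test_monotone_in_cutoff(self, groove):
        receptor, peptide, _ = groove
        small = hs.contact_residues(receptor, peptide, ContactParams(4.0))
        large = hs.contact_residues(receptor, peptide, ContactParams(6.0))
        assert small.pair_keys <= large.pair_keys

    def test_sidechain_pairs_subset_of_all_atom_pairs(self, groove):
        receptor, peptide, _ = groove
        sc = hs.contact_residues(receptor, peptide, ContactParams(5.0, True))
        aa = hs.contact_residues(receptor, peptide, ContactParams(5.0, False))
        assert sc.pair_keys <= aa.pair_keys

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(11)
        def random_structure(chain, n_res):
            atoms = []
            serial = 1
            for r in range(1, n_res + 1):
                center = rng.uniform(-8, 8, 3)
                resname = rng.choice(["LEU", "GLY", "SER", "TRP"])
                for name in (["N", "CA", "CB"] if resname != "GLY" else ["N", "CA"]):
                    atoms.append(hs.Atom(serial, name, "C", str(resname), r, chain,
                                         center + rng.normal(0, 1.2, 3), radius=1.7))
                    serial += 1
            return hs.Structure(atoms)

        a, b = random_structure("A", 12), random_structure("B", 12)
        cm = hs.contact_residues(a, b, ContactParams(5.0, True))
        expected = {}
        for at_a in a.atoms:
            if not at_a.is_sidechain:
                continue
            for at_b in b.atoms:
                if not at_b.is_sidechain:
                    continue
                d = float(np.linalg.norm(at_a.position - at_b.position))
                key = (at_a.residue_key, at_b.residue_key)
                if d <= 5.0 and d < expected.get(key, np.inf):
                    expected[key] = d
        assert cm.pair_keys == set(expected)
        for p in cm.pairs:
            assert p.min_distance == pytest.approx(expected[(p.receptor.key, p.peptide.key)])


class TestHelixFaceTriples:
    def test_i_i3_i7_pattern(self):
        triples = hs.helix_face_triples(contact_map_for({5, 8, 12}))
        assert len(triples) == 1
        assert [r.number for r in triples[0].residues] == [5, 8, 12]
        assert triples[0].pattern == "i,i+3,i+7"

    def test_i_i4_i7_pattern(self):
        triples = hs.helix_face_triples(contact_map_for({19, 23, 26}))
        assert len(triples) == 1
        assert [r.number for r in triples[0].residues] == [19, 23, 26]
        assert triples[0].pattern == "i,i+4,i+7"

    def test_no_valid_spacing_gives_empty_list(self):
        assert hs.helix_face_triples(contact_map_for({1, 2})) == []

    def test_both_patterns_reported_when_present(self):
        triples = hs.helix_face_triples(contact_map_for({1, 4, 5, 8}))
        patterns = {(tuple(r.number for r in t.residues), t.pattern) for t in triples}
        assert patterns == {((1, 4, 8), "i,i+3,i+7"), ((1, 5, 8), "i,i+4,i+7")}

    def test_invalid_offsets_rejected(self):
        from helixsurf.contacts import HelixFaceTriple

        refs = tuple(ResidueRef("P", n, "", "ALA") for n in (1, 3, 8))
        with pytest.raises(ValueError):
            HelixFaceTriple(refs, "i,i+3,i+7")


class TestHotspotTally:
    def test_counts_and_ordering(self):
        m1 = contact_map_for({5, 8}, chain="A")
        m2 = contact_map_for({8, 12}, chain="A")
        # residues here live on the peptide side of the map; build receptor-side maps
        def rmap(numbers):
            pep = ResidueRef("P", 1, "", "ALA")
            return ContactMap([
                ContactPair(ResidueRef("A", n, "", "MET"), pep, 4.0) for n in numbers
            ])

        table = hs.receptor_hotspot_tally([rmap({92, 124}), rmap({124, 141})])
        assert table.iloc[0]["residue"] == "MET124"
        assert table.iloc[0]["n_complexes"] == 2
        assert set(table["n_complexes"]) == {1, 2}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hs.receptor_hotspot_tally([])
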