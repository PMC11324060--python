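import pytest
from rdkit import Chem

from pnpkit.catalog import build_catalog
from pnpkit.combinations import (
    DISCARD,
    TYPED,
    CombinationEdge,
    FragmentHit,
    analyze_molecule,
    build_fcgs,
    canonical_signature,
    classify_all_pairs,
    classify_pair,
    find_fragment_hits,
    resolve_containment,
)

RING_CATALOG = build_catalog(["C1CCCCC1", "C1CCCC1", "c1ccncc1"])
CYCLOHEXANE, CYCLOPENTANE, PYRIDINE = 0, 1, 2


def _classified_pairs(smiles, catalog=RING_CATALOG, cutoff=3):
    mol = Chem.MolFromSmiles(smiles)
    hits = resolve_containment(find_fragment_hits(mol, catalog))
    out = []
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            forward = classify_pair(hits[i], hits[j], mol, cutoff)
            backward = classify_pair(hits[j], hits[i], mol, cutoff)
            assert forward == backward, "classification must be symmetric"
            out.append((hits[i].frag_id, hits[j].frag_id, forward))
    return out


class TestFindFragmentHits:
    def test_catalog_fragment_matches_itself(self):
        mol = Chem.MolFromSmiles("c1ccncc1")
        hits = find_fragment_hits(mol, RING_CATALOG)
        assert len(hits) == 1
        assert hits[0].atom_ids == frozenset(range(mol.GetNumAtoms()))

    def test_two_occurrences_numbered(self):
        mol = Chem.MolFromSmiles("c1ccncc1CCc1ccncc1")
        hits = find_fragment_hits(mol, RING_CATALOG)
        assert [(h.frag_id, h.occurrence) for h in hits] == [(PYRIDINE, 0), (PYRIDINE, 1)]
        assert hits[0].atom_ids != hits[1].atom_ids

    def test_no_hits_is_valid(self):
        assert find_fragment_hits(Chem.MolFromSmiles("C1CC1"), RING_CATALOG) == []


class TestClassifyPair:
    def test_spiro_single_shared_atom(self):
        assert _classified_pairs("C1CCC2(CC1)CCCC2") == [(CYCLOHEXANE, CYCLOPENTANE, "fs")]

    def test_edge_fusion_decalin(self):
        assert _classified_pairs("C1CCC2CCCCC2C1") == [(CYCLOHEXANE, CYCLOHEXANE, "fe")]

    def test_bridge_fusion_norbornane(self):
        pairs = _classified_pairs("C1CC2CCC1C2")
        # the two 5-rings share a 3-atom bridge; the perimeter 6-ring also hits
        assert (CYCLOPENTANE, CYCLOPENTANE, "fb") in pairs
        assert all(t == "fb" for _, _, t in pairs)

    def test_monopodal_two_bond_linker(self):
        assert _classified_pairs("c1ccncc1CCc1ccncc1") == [(PYRIDINE, PYRIDINE, "cm")]

    def test_monopodal_direct_bond(self):
        assert _classified_pairs("c1ccncc1-c1ccncc1") == [(PYRIDINE, PYRIDINE, "cm")]

    def test_cutoff_discards_distant_pair(self):
        # five CH2 linker atoms = a 6-bond bridge: beyond cutoff 3 -> no edge,
        # but typed cm once the cutoff admits the bridge
        mol = Chem.MolFromSmiles("c1ccncc1CCCCCc1ccncc1")
        hits = resolve_containment(find_fragment_hits(mol, RING_CATALOG))
        assert classify_pair(hits[0], hits[1], mol, cutoff=3) == "cfc"
        assert classify_pair(hits[0], hits[1], mol, cutoff=6) == "cm"

    def test_bipodal_edge_adjacent_attachments(self, toy_catalog):
        # constructed cbe: two direct bonds from adjacent atoms on each ring
        from pnpkit.synthetic import compose_molecule

        frag = next(e for e in toy_catalog if e.smiles == "c1ccncc1")
        composed = compose_molecule(frag, frag, "cbe")
        assert composed is not None
        pairs = _classified_pairs(composed.smiles, toy_catalog)
        assert (frag.frag_id, frag.frag_id, "cbe") in pairs

    def test_bipodal_spiro_shared_attachment_atom(self):
        # one cyclopentane carbon bonds a pyridine directly and, via a CH2,
        # the adjacent pyridine atom: two attachment pairs sharing an atom
        assert _classified_pairs("C1C2(CCCC2)c2ncccc21") == [
            (CYCLOPENTANE, PYRIDINE, "cbs")
        ]

    def test_exactly_one_code_per_pair(self, toy_catalog, composites):
        for comp in composites[::7]:
            mol = Chem.MolFromSmiles(comp.smiles)
            hits = resolve_containment(find_fragment_hits(mol, toy_catalog))
            for i in range(len(hits)):
                for j in range(i + 1, len(hits)):
                    code = classify_pair(hits[i], hits[j], mol)
                    assert code in TYPED + DISCARD


class TestContainment:
    def test_contained_hit_discarded(self, toy_catalog):
        # quinoline contains pyridine: the pyridine sub-hit must not survive
        mol = Chem.MolFromSmiles("c1ccc2ncccc2c1")
        hits = resolve_containment(find_fragment_hits(mol, toy_catalog))
        quinoline = next(e for e in toy_catalog if "2n" in e.smiles or "n2" in e.smiles)
        assert [h.frag_id for h in hits] == [quinoline.frag_id]


class TestSignatures:
    def _hit(self, frag_id, occ, atoms):
        return FragmentHit(frag_id, occ, frozenset(atoms))

    def test_min_max_ordering(self):
        edge = CombinationEdge(self._hit(7, 0, {1}), self._hit(3, 0, {2}), "cm")
        assert edge.edge_string() == "3:7:cm"

    def test_sorted_join(self):
        edges = [
            CombinationEdge(self._hit(5, 0, {1}), self._hit(9, 0, {2}), "fe"),
            CombinationEdge(self._hit(9, 0, {2}), self._hit(3, 0, {3}), "cm"),
        ]
        assert canonical_signature(edges) == "3:9:cm|5:9:fe"

    def test_occurrence_dropped_and_deduplicated(self):
        edges = [
            CombinationEdge(self._hit(1, 0, {1}), self._hit(2, 0, {2}), "cm"),
            CombinationEdge(self._hit(1, 1, {3}), self._hit(2, 1, {4}), "cm"),
        ]
        assert canonical_signature(edges) == "1:2:cm"

    def test_stable_under_smiles_roundtrip(self, toy_catalog, composites):
        for comp in composites[::11]:
            first = analyze_molecule(comp.smiles, toy_catalog)
            mol = Chem.MolFromSmiles(comp.smiles)
            rendered = Chem.MolToSmiles(mol, rootedAtAtom=mol.GetNumAtoms() - 1)
            second = analyze_molecule(rendered, toy_catalog)
            assert first.signatures == second.signatures


class TestBuildFcgs:
    def _hit(self, frag_id, occ):
        return FragmentHit(frag_id, occ, frozenset({frag_id * 10 + occ}))

    def test_single_edge_single_fcg(self):
        a, b = self._hit(1, 0), self._hit(2, 0)
        fcgs = build_fcgs([a, b], [CombinationEdge(a, b, "cm")])
        assert len(fcgs) == 1 and fcgs[0].signature == "1:2:cm"

    def test_disjoint_pairs_give_two_fcgs(self):
        a, b, c, d = (self._hit(i, 0) for i in range(1, 5))
        edges = [CombinationEdge(a, b, "cm"), CombinationEdge(c, d, "fe")]
        fcgs = build_fcgs([a, b, c, d], edges)
        assert [f.signature for f in fcgs] == ["1:2:cm", "3:4:fe"]

    def test_isolated_hits_yield_nothing(self):
        assert build_fcgs([self._hit(1, 0)], []) == []
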