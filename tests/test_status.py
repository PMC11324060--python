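"""Status assignment against a constructed 3-fragment universe.

The universe uses pyridine (0), piperidine (1) and pyrrolidine (2). Members
are single-linker (monopodal) composites, so every expected signature is a
hand-written ``a:b:cm`` string; at graph level the multi-edge molecule has
the concatenated signature. The NP reference contains molecule B only, so
``0:2:cm`` is the one "natural" combination.
"""

import pytest

from pnpkit.catalog import build_catalog
from pnpkit.combinations import analyze_molecule
from pnpkit.standardize import MoleculeRecord, PipelineConfig, standardize_record
from pnpkit.status import NPReference, build_np_reference, classify_molecule

CATALOG = build_catalog(["c1ccncc1", "C1CCNCC1", "C1CCNC1"])

#: hand-computed: smiles, expected edge strings, expected status vs {0:2:cm}
UNIVERSE = [
    ("A", "c1ccncc1C1CCNCC1", ["0:1:cm"], "PNP"),  # novel combination
    ("B", "c1ccncc1C1CCNC1", ["0:2:cm"], "NP"),  # the reference NP itself
    ("D", "c1ccncc1CC1CCNC1", ["0:2:cm"], "NPL"),  # known combination, new compound
    # E: pyridine linked to both rings from para positions (the two amine
    # rings are 4 bonds apart through the pyridine -> no edge between them);
    # one known + one novel combination -> PNP wins
    ("E", "C1CCNC1c1ccnc(C2CCNCC2)c1", ["0:1:cm", "0:2:cm"], "PNP"),
    ("F", "c1ccncc1", [], "NonPNP"),  # single fragment, no combination
    ("G", "C1CNC1", [], "NonPNP"),  # ring without any catalog hit
]


def _record(source_id, smiles):
    return standardize_record(MoleculeRecord(source_id, smiles))


@pytest.fixture(scope="module")
def reference():
    np_record = _record("np_B", "c1ccncc1C1CCNC1")
    return build_np_reference([np_record], CATALOG, PipelineConfig())


class TestTruthTable:
    @pytest.mark.parametrize("name,smiles,expected_edges,expected_status", UNIVERSE)
    def test_edge_level(self, reference, name, smiles, expected_edges, expected_status):
        rec = _record(name, smiles)
        analysis = analyze_molecule(rec.smiles_std, CATALOG)
        assert analysis.edge_strings == expected_edges
        assert classify_molecule(rec, analysis.fcgs, reference, "edge") == expected_status

    @pytest.mark.parametrize("name,smiles,expected_edges,expected_status", UNIVERSE)
    def test_graph_level(self, name, smiles, expected_edges, expected_status):
        config = PipelineConfig(fcg_compare_level="graph")
        reference = build_np_reference(
            [_record("np_B", "c1ccncc1C1CCNC1")], CATALOG, config
        )
        rec = _record(name, smiles)
        analysis = analyze_molecule(rec.smiles_std, CATALOG)
        assert classify_molecule(rec, analysis.fcgs, reference, "graph") == expected_status

    def test_identity_wins_over_novel_combination(self, reference):
        # put E itself into the NP identity set: despite its novel 0:1:cm
        # combination it is an NP
        rec = _record("E", "C1CCNC1c1ccnc(C2CCNCC2)c1")
        reference2 = NPReference(
            np_inchikeys=reference.np_inchikeys | {rec.inchikey},
            np_signatures=set(reference.np_signatures),
        )
        analysis = analyze_molecule(rec.smiles_std, CATALOG)
        assert classify_molecule(rec, analysis.fcgs, reference2) == "NP"

    def test_duplicate_of_np_is_np(self, reference):
        rec = _record("B_copy", "C1NCCC1c1cccnc1")  # same molecule, new rendering
        analysis = analyze_molecule(rec.smiles_std, CATALOG)
        assert classify_molecule(rec, analysis.fcgs, reference) == "NP"

    def test_failed_record_is_nonpnp(self, reference):
        rec = _record("acyclic", "CCCC")
        assert rec.passed_filters is False
        assert classify_molecule(rec, [], reference) == "NonPNP"


class TestReferenceProperties:
    def test_monotone_enlarging_signatures(self, reference):
        rec = _record("A", "c1ccncc1C1CCNCC1")
        analysis = analyze_molecule(rec.smiles_std, CATALOG)
        assert classify_molecule(rec, analysis.fcgs, reference) == "PNP"
        bigger = NPReference(
            np_inchikeys=set(reference.np_inchikeys),
            np_signatures=reference.np_signatures | {"0:1:cm"},
        )
        assert classify_molecule(rec, analysis.fcgs, bigger) == "NPL"

    def test_duplicate_nps_no_double_counting(self):
        recs = [_record("np1", "c1ccncc1C1CCNC1"), _record("np2", "c1ccncc1C1CCNC1")]
        ref = build_np_reference(recs, CATALOG, PipelineConfig())
        assert len(ref.np_inchikeys) == 1
        assert ref.np_signatures == {"0:2:cm"}

    def test_np_without_combinations_contributes_identity_only(self):
        rec = _record("np_plain", "c1ccncc1")
        ref = build_np_reference([rec], CATALOG, PipelineConfig())
        assert ref.np_inchikeys == {rec.inchikey}
        assert ref.np_signatures == set()

    def test_empty_library_fatal(self):
        with pytest.raises(ValueError):
            build_np_reference([], CATALOG, PipelineConfig())

    def test_roundtrip_save_load(self, tmp_path, reference):
        path = tmp_path / "ref.json"
        reference.save(path)
        loaded = NPReference.load(path)
        assert loaded.np_inchikeys == reference.np_inchikeys
        assert loaded.np_signatures == reference.np_signatures


def test_partition_over_statuses(small_library, toy_catalog):
    """Statuses of a deduplicated library partition it: the four counts sum
    to the library size."""
    from pnpkit.pipeline import standardize_library
    from pnpkit.standardize import deduplicate

    library, np_library, _ = small_library
    config = PipelineConfig()
    unique, _n = deduplicate(standardize_library(list(library), config))
    np_unique, _ = deduplicate(standardize_library(list(np_library), config))
    ref = build_np_reference(np_unique, toy_catalog, config)
    counts = {s: 0 for s in ("PNP", "NPL", "NP", "NonPNP")}
    for rec in unique:
        if rec.passed_filters and rec.smiles_std:
            analysis = analyze_molecule(rec.smiles_std, toy_catalog)
            counts[classify_molecule(rec, analysis.fcgs, ref)] += 1
        else:
            counts["NonPNP"] += 1
    assert sum(counts.values()) == len(unique)
    assert all(v > 0 for v in counts.values())
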