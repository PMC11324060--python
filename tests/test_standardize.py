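import time

import pytest
from rdkit import Chem

from pnpkit.standardize import (
    ChunkFailure,
    MoleculeRecord,
    PipelineConfig,
    StandardizationError,
    apply_filters,
    chunked_map,
    deduplicate,
    deglycosylate,
    read_molecule_table,
    standardize_record,
    standardize_structure,
)


class TestStandardizeStructure:
    def test_stereo_stripped_matches_racemic_inchikey(self):
        smiles, inchikey = standardize_structure("C[C@H](N)C(=O)O")
        _, racemic_key = standardize_structure("CC(N)C(=O)O")
        assert inchikey == racemic_key
        assert "@" not in smiles and "/" not in smiles

    def test_largest_organic_component_kept(self):
        smiles, _ = standardize_structure("c1ccccc1.[Na+].[Cl-]")
        assert smiles == "c1ccccc1"

    def test_atom_order_independent(self):
        a = standardize_structure("OC(=O)c1ccccc1N")
        b = standardize_structure("Nc1ccccc1C(O)=O")
        assert a == b

    def test_idempotent(self):
        first, key1 = standardize_structure("C[C@@H](O)c1ccc(Cl)cc1.[K+].[Br-]")
        second, key2 = standardize_structure(first)
        assert (first, key1) == (second, key2)

    def test_unparseable_raises_with_source_id(self):
        with pytest.raises(StandardizationError) as err:
            standardize_structure("not-a-smiles(((", source_id="x7")
        assert err.value.source_id == "x7"

    def test_inchikey_layout(self):
        _, inchikey = standardize_structure("c1ccncc1")
        parts = inchikey.split("-")
        assert (len(parts[0]), len(parts[1]), len(parts[2])) == (14, 10, 1)


class TestDeglycosylate:
    def test_salicin_gives_aglycone(self):
        # oracle: removing the pyranose ring and its hydroxyls by hand leaves
        # 2-(hydroxymethyl)phenol
        salicin = Chem.CanonSmiles("OCC1=CC=CC=C1OC1OC(CO)C(O)C(O)C1O")
        assert deglycosylate(salicin) == Chem.CanonSmiles("OCc1ccccc1O")

    def test_no_sugar_unchanged(self):
        assert deglycosylate("OC1CCCCC1") == "OC1CCCCC1"

    def test_diglycoside_both_sugars_removed(self):
        # second glucose on the 6-position of the first; iterative removal
        # must peel the terminal sugar first, then the inner one
        dig = Chem.CanonSmiles(
            "OCC1=CC=CC=C1OC1OC(COC2OC(CO)C(O)C(O)C2O)C(O)C(O)C1O"
        )
        assert deglycosylate(dig) == Chem.CanonSmiles("OCc1ccccc1O")

    def test_bare_sugar_kept_when_removal_would_empty(self):
        methyl_glucoside = Chem.CanonSmiles("COC1OC(CO)C(O)C(O)C1O")
        out = deglycosylate(methyl_glucoside)
        # aglycone is methanol, which is non-empty -> removal happens
        assert out == "CO"

    def test_non_sugar_ring_with_one_hydroxyl_untouched(self):
        smi = Chem.CanonSmiles("OC1CCOC1Oc1ccccc1")  # only 1 exocyclic OH
        assert deglycosylate(smi) == smi


class TestFilters:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCCCCC", False),  # acyclic
            ("OC1CCCCC1", True),  # 1 ring, small
            ("C1CCCCC1" + "C" * 70, False),  # ring but MW >= 1000
        ],
    )
    def test_ring_and_mw_filters(self, smiles, expected):
        rec = standardize_record(MoleculeRecord("m", smiles))
        assert apply_filters(rec) is expected
        assert rec.passed_filters is expected


class TestDeduplicate:
    def test_enantiomers_collapse(self):
        recs = [
            standardize_record(MoleculeRecord("a", "C[C@H](N)C(=O)O")),
            standardize_record(MoleculeRecord("b", "C[C@@H](N)C(=O)O")),
        ]
        unique, n_dup = deduplicate(recs)
        assert len(unique) == 1 and n_dup == 1
        assert unique[0].source_id == "a"  # first occurrence kept

    def test_partition_invariant(self):
        smileses = ["c1ccccc1", "c1ccncc1", "c1ccccc1", "CCO", "c1ccncc1", "CCO"]
        recs = [
            standardize_record(MoleculeRecord(f"m{i}", s)) for i, s in enumerate(smileses)
        ]
        unique, n_dup = deduplicate(recs)
        assert len(unique) + n_dup == len(recs)
        assert [r.source_id for r in unique] == ["m0", "m1", "m3"]

    def test_empty(self):
        assert deduplicate([]) == ([], 0)


class TestReadMoleculeTable:
    def test_tsv_counts_and_rejections(self, tmp_path):
        path = tmp_path / "lib.tsv"
        path.write_text("id\tsmiles\na\tCCO\nb\tnot(((\nc\tc1ccccc1\n")
        records = read_molecule_table(path, "smiles-tsv")
        assert [r.source_id for r in records] == ["a", "c"]

    def test_sdf_duplicates_kept(self, tmp_path):
        mol = Chem.MolFromSmiles("c1ccccc1")
        path = tmp_path / "lib.sdf"
        with Chem.SDWriter(str(path)) as writer:
            for _ in range(2):
                writer.write(mol)
        records = read_molecule_table(path, "sdf")
        assert len(records) == 2  # dedup is a separate step

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_molecule_table(tmp_path / "absent.tsv")

    def test_all_invalid_fatal(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tsmiles\na\t)))\n")
        with pytest.raises(ValueError):
            read_molecule_table(path)


class TestChunkedMap:
    def test_chunk_size_never_changes_results(self):
        records = list(range(100))
        op = lambda x: x * x
        outputs = [
            chunked_map(records, op, PipelineConfig(chunk_size=cs))
            for cs in (1, 7, 100)
        ]
        assert outputs[0] == outputs[1] == outputs[2] == [x * x for x in records]

    def test_timeout_marks_record_and_continues(self):
        def slow_on_two(x):
            if x == 2:
                time.sleep(1.0)
            return x

        config = PipelineConfig(chunk_size=2, timeout_s=0.2)
        results = chunked_map([1, 2, 3], slow_on_two, config)
        assert results[0] == 1 and results[2] == 3
        assert isinstance(results[1], ChunkFailure)
        assert "timeout" in results[1].reason

    def test_exception_becomes_failure_marker(self):
        def boom(x):
            if x == "bad":
                raise RuntimeError("nope")
            return x

        results = chunked_map(["ok", "bad"], boom, PipelineConfig())
        assert results[0] == "ok"
        assert isinstance(results[1], ChunkFailure)

    def test_empty_input(self):
        assert chunked_map([], lambda x: x, PipelineConfig()) == []


def test_config_validation():
    with pytest.raises(ValueError):
        PipelineConfig(timeout_s=0)
    with pytest.raises(ValueError):
        PipelineConfig(chunk_size=0)
    with pytest.raises(ValueError):
        PipelineConfig(fcg_compare_level="both")
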