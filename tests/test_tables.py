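"""Domain types, CSV/TSV I/O round-trips, and the lipid shorthand grammar."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metopls import (
    DuplicateIdError,
    FormatError,
    MetaboliteTable,
    PanelAnnotation,
    parse_lipid_id,
    read_design,
    read_lod,
    read_table,
    write_design,
    write_lod,
    write_table,
)
from metopls.simulate import INDEX_ANALYTES
from metopls.tables import annotation_from_id, read_annotations, write_annotations


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTable:
    def test_samples_as_rows(self, tmp_path):
        p = _write(tmp_path, "t.csv", "sample,Ala,Gln\ns1,1,2\ns2,3,4\ns3,5,6\n")
        t = read_table(p)
        assert t.sample_ids == ["s1", "s2", "s3"]
        assert t.metabolite_ids == ["Ala", "Gln"]
        assert t.data.loc["s2", "Gln"] == 4

    def test_transposed_orientation_gives_identical_table(self, tmp_path):
        a = _write(tmp_path, "a.csv", "sample,Ala,Gln\ns1,1,2\ns2,3,4\ns3,5,6\n")
        b = _write(tmp_path, "b.csv", "metabolite,s1,s2,s3\nAla,1,3,5\nGln,2,4,6\n")
        ta = read_table(a)
        tb = read_table(b, orientation="metabolites_as_rows")
        assert ta.equals(tb)

    def test_duplicate_metabolite_rejected(self, tmp_path):
        p = _write(tmp_path, "t.csv", "sample,Ala,Ala\ns1,1,2\n")
        with pytest.raises(DuplicateIdError):
            read_table(p)

    def test_ragged_rows_rejected(self, tmp_path):
        p = _write(tmp_path, "t.csv", "sample,Ala,Gln\ns1,1,2\ns2,3\n")
        with pytest.raises(FormatError):
            read_table(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = _write(tmp_path, "t.csv", "sample,Ala\ns1,oops\n")
        with pytest.raises(FormatError):
            read_table(p)

    def test_missing_token_becomes_nan(self, tmp_path):
        p = _write(tmp_path, "t.csv", "sample,Ala\ns1,NA\ns2,2\n")
        t = read_table(p)
        assert np.isnan(t.data.loc["s1", "Ala"])


class TestWriteTable:
    def test_round_trip(self, tmp_path, rng):
        vals = rng.uniform(0.001, 500.0, size=(6, 9))
        t = MetaboliteTable(vals, [f"s{i}" for i in range(6)], [f"m{j}" for j in range(9)])
        path = tmp_path / "t.csv"
        write_table(t, path)
        assert read_table(path).equals(t)

    def test_missing_written_as_token(self, tmp_path):
        vals = np.array([[1.0, np.nan]])
        t = MetaboliteTable(vals, ["s1"], ["a", "b"])
        path = tmp_path / "t.csv"
        write_table(t, path)
        assert "NA" in path.read_text()
        assert read_table(path).equals(t)

    def test_empty_table_round_trips(self, tmp_path):
        t = MetaboliteTable(np.empty((0, 2)), [], ["a", "b"])
        path = tmp_path / "t.csv"
        write_table(t, path)
        back = read_table(path)
        assert back.shape == (0, 2)
        assert back.metabolite_ids == ["a", "b"]

    def test_tsv_round_trip(self, tmp_path):
        t = MetaboliteTable([[1.5, 2.5]], ["s1"], ["a", "b"])
        path = tmp_path / "t.tsv"
        write_table(t, path)
        assert read_table(path).equals(t)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False, width=64),
            min_size=4,
            max_size=4,
        )
    )
    def test_round_trip_preserves_values_to_12_digits(self, tmp_path_factory, values):
        tmp = tmp_path_factory.mktemp("rt")
        t = MetaboliteTable([values], ["s1"], [f"m{j}" for j in range(4)])
        path = tmp / "t.csv"
        write_table(t, path)
        back = read_table(path)
        np.testing.assert_allclose(back.values(), t.values(), rtol=1e-11)


class TestMetaboliteTable:
    def test_rejects_duplicate_sample_ids(self):
        with pytest.raises(DuplicateIdError):
            MetaboliteTable([[1.0], [2.0]], ["s1", "s1"], ["a"])

    def test_rejects_negative_and_infinite(self):
        with pytest.raises(FormatError):
            MetaboliteTable([[-1.0]], ["s1"], ["a"])
        with pytest.raises(FormatError):
            MetaboliteTable([[np.inf]], ["s1"], ["a"])

    def test_ids_whitespace_trimmed(self):
        t = MetaboliteTable([[1.0]], [" s1 "], [" Ala "])
        assert t.sample_ids == ["s1"] and t.metabolite_ids == ["Ala"]


class TestLipidGrammar:
    @pytest.mark.parametrize(
        "mid, subclass, carbons, dbs, oh",
        [
            ("PC aa C36:4", "PC_aa", 36, 4, False),
            ("PC ae C38:6", "PC_ae", 38, 6, False),
            ("lysoPC a C18:1", "lysoPC", 18, 1, False),
            ("SM C16:0", "SM", 16, 0, False),
            ("SM (OH) C22:2", "SM_OH", 22, 2, True),
        ],
    )
    def test_parses_shorthand(self, mid, subclass, carbons, dbs, oh):
        assert parse_lipid_id(mid) == (subclass, carbons, dbs, oh)

    @pytest.mark.parametrize("bad", ["PC C36:4", "SM OH C22:2", "PC aa 36:4", "Ala"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormatError):
            parse_lipid_id(bad)

    def test_subclass_klass_consistency_enforced(self):
        with pytest.raises(FormatError):
            PanelAnnotation("x", "sphingolipid", "PC_aa", 36, 4, False)
        with pytest.raises(FormatError):
            PanelAnnotation("x", "glycerophospholipid", "SM", 16, 0, False)

    def test_lipid_subclass_requires_positive_carbons(self):
        with pytest.raises(FormatError):
            PanelAnnotation("x", "sphingolipid", "SM", 0, 0, False)


class TestDefaultPanel:
    def test_partition_and_uniqueness(self, panel):
        assert len(panel) == 188
        assert panel.count_by_klass() == {
            "acylcarnitine": 40,
            "amino_acid": 21,
            "biogenic_amine": 21,
            "glycerophospholipid": 90,
            "sphingolipid": 15,
            "sugar": 1,
        }
        assert len(set(panel.ids)) == 188

    def test_every_lipid_id_parses(self, panel):
        for a in panel:
            if a.klass in ("glycerophospholipid", "sphingolipid"):
                sub, c, d, oh = parse_lipid_id(a.metabolite_id)
                assert (sub, c, d, oh) == (
                    a.subclass,
                    a.total_carbons,
                    a.total_double_bonds,
                    a.hydroxylated,
                )

    def test_index_analytes_present(self, panel):
        for mid in INDEX_ANALYTES:
            assert mid in panel
        assert panel["SM (OH) C22:1"].hydroxylated

    def test_annotations_round_trip(self, panel, tmp_path):
        path = tmp_path / "ann.csv"
        write_annotations(panel, path)
        back = read_annotations(path)
        assert back.to_frame().equals(panel.to_frame())


class TestDefaultDesign:
    def test_measurement_count_and_bridges(self, design):
        assert len(design) == 40  # 7x5 samples + 5 wild-type rerun in batch 2
        bridge_batches = {}
        for r in design:
            if r.is_bridge:
                bridge_batches.setdefault(r.sample_id, set()).add(r.batch)
        assert len(bridge_batches) == 5
        assert all(len(b) == 2 for b in bridge_batches.values())

    def test_severity_ranks_order(self, design):
        ranks = design.severity_ranks
        assert ranks["Opa1+/+"] == ranks["ISO1"] == 0
        assert ranks["I382M"] < ranks["D603H"] < ranks["G439V"] < ranks["R445H"]
        assert ranks["R445H"] < ranks["Opa1-/-"]

    def test_round_trip(self, design, tmp_path):
        path = tmp_path / "design.csv"
        write_design(design, path)
        back = read_design(path)
        assert back.to_frame().equals(design.to_frame())

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("sample_id,group\ns1,G\n")
        with pytest.raises(FormatError):
            read_design(p)


class TestLOD:
    def test_round_trip(self, tmp_path):
        lods = {"Ala": 0.05, "PC aa C36:4": 1.25e-3}
        path = tmp_path / "lod.csv"
        write_lod(lods, path)
        back = read_lod(path)
        assert back.keys() == lods.keys()
        np.testing.assert_allclose(list(back.values()), list(lods.values()), rtol=1e-11)

    def test_nonpositive_lod_rejected(self, tmp_path):
        p = tmp_path / "lod.csv"
        p.write_text("metabolite_id,lod\nAla,0\n")
        with pytest.raises(FormatError):
            read_lod(p)
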