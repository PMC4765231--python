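import sqlite3

import pytest

from molcarto import (
    AMINO_ACIDS,
    default_registry,
    fasa_h,
    load_database,
    lookup,
    write_codebook,
    write_database,
)
from molcarto.errors import (
    DatabaseError,
    MolcartoWarning,
    UnknownDescriptorError,
    UnpopulatedDescriptorError,
)

EXPECTED_CATEGORY_COUNTS = {
    "adjacency and distance matrix": 33,
    "atom and bond counts": 41,
    "conformation dependent charge": 18,
    "Kier and Hall connectivity and kappa shape indices": 16,
    "MOPAC": 21,
    "partial charge": 48,
    "pharmacophore features": 12,
    "potential energy": 11,
    "physical properties": 16,
    "subdivided surface areas": 18,
    "surface area, volume and shape": 94,
}


class TestDefaultRegistry:
    def test_taxonomy_counts(self):
        reg = default_registry()
        assert reg.category_counts() == EXPECTED_CATEGORY_COUNTS
        assert len(reg) == sum(EXPECTED_CATEGORY_COUNTS.values()) == 328
        assert len(reg.categories) == 11

    def test_populated_records_cover_all_amino_acids(self):
        reg = default_registry()
        populated = reg.populated_names()
        assert "Weight" in populated and "FASA_H" in populated
        for name in populated:
            assert set(reg.records[name].values) == set(AMINO_ACIDS)

    def test_weight_values_match_standard_masses(self):
        reg = default_registry()
        assert lookup(reg, "Weight", "GLY") == pytest.approx(75.07, abs=0.01)
        assert lookup(reg, "Weight", "TRP") == pytest.approx(204.23, abs=0.01)

    def test_charge_signs(self):
        reg = default_registry()
        assert lookup(reg, "FCharge", "ASP") == -1.0
        assert lookup(reg, "FCharge", "LYS") == 1.0
        assert lookup(reg, "FCharge", "SER") == 0.0

    def test_fasa_h_consistent_with_asa_tables(self):
        reg = default_registry()
        for aa in AMINO_ACIDS:
            expected = fasa_h(lookup(reg, "ASA_H", aa), lookup(reg, "ASA", aa))
            assert lookup(reg, "FASA_H", aa) == pytest.approx(expected, abs=5e-5)
            assert 0.0 < lookup(reg, "FASA_H", aa) < 1.0
        # leucine's surface is far more hydrophobic than aspartate's
        assert lookup(reg, "FASA_H", "LEU") > lookup(reg, "FASA_H", "ASP")


class TestSqliteRoundTrip:
    def test_write_then_load_preserves_everything(self, tmp_path):
        reg = default_registry()
        db = tmp_path / "props.sqlite"
        write_database(reg, db)
        back = load_database(db)
        assert len(back) == 328
        assert back.category_counts() == EXPECTED_CATEGORY_COUNTS
        for name in reg.populated_names():
            for aa in AMINO_ACIDS:
                assert back.records[name].values[aa] == reg.records[name].values[aa]
        assert sorted(back.populated_names()) == sorted(reg.populated_names())

    def _custom_db(self, path, n_aas=20):
        con = sqlite3.connect(path)
        con.execute("CREATE TABLE descriptors "
                    "(name TEXT, category TEXT, units TEXT, description TEXT)")
        con.execute("CREATE TABLE aa_values "
                    "(descriptor_name TEXT, amino_acid TEXT, value REAL)")
        con.execute("INSERT INTO descriptors VALUES ('myprop', 'custom', '', '')")
        for aa in AMINO_ACIDS[:n_aas]:
            con.execute("INSERT INTO aa_values VALUES ('myprop', ?, 1.5)", (aa,))
        con.commit()
        con.close()
        return path

    def test_custom_database_replaces_default(self, tmp_path):
        reg = load_database(self._custom_db(tmp_path / "c.sqlite"))
        assert len(reg) == 1
        assert lookup(reg, "myprop", "ALA") == 1.5

    def test_partial_record_rejected_naming_gap(self, tmp_path):
        with pytest.raises(DatabaseError, match="VAL"):
            load_database(self._custom_db(tmp_path / "p.sqlite", n_aas=19))

    def test_schema_mismatch(self, tmp_path):
        path = tmp_path / "bad.sqlite"
        con = sqlite3.connect(path)
        con.execute("CREATE TABLE wrong (a TEXT)")
        con.commit()
        con.close()
        with pytest.raises(DatabaseError, match="schema"):
            load_database(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(DatabaseError, match="not found"):
            load_database(tmp_path / "absent.sqlite")


class TestLookup:
    def test_unknown_descriptor_lists_near_matches(self):
        with pytest.raises(UnknownDescriptorError, match="Weight"):
            lookup(default_registry(), "Wight", "ALA")

    def test_unknown_descriptor_no_neighbours(self):
        with pytest.raises(UnknownDescriptorError):
            lookup(default_registry(), "zzzz_nothing_like_this", "ALA")

    def test_unpopulated_descriptor_errors_clearly(self):
        with pytest.raises(UnpopulatedDescriptorError, match="no values"):
            lookup(default_registry(), "balabanJ", "ALA")

    def test_nonstandard_residue_skips_with_warning(self):
        with pytest.warns(MolcartoWarning, match="MSE"):
            assert lookup(default_registry(), "Weight", "MSE") is None

    def test_nonstandard_residue_error_policy(self):
        with pytest.raises(UnknownDescriptorError):
            lookup(default_registry(), "Weight", "MSE", on_unknown_residue="error")


class TestFasaH:
    @pytest.mark.parametrize("h,t,expected", [(50, 100, 0.5), (0, 100, 0.0),
                                              (100, 100, 1.0)])
    def test_ratio(self, h, t, expected):
        assert fasa_h(h, t) == expected

    @pytest.mark.parametrize("h,t", [(1, 0), (10, -5), (101, 100), (-1, 100)])
    def test_invalid_inputs(self, h, t):
        with pytest.raises(ValueError):
            fasa_h(h, t)


class TestCodebook:
    def test_codebook_lists_every_descriptor(self, tmp_path):
        reg = default_registry()
        path = tmp_path / "codebook.txt"
        write_codebook(reg, path)
        text = path.read_text()
        assert text.count("\n- ") == 328
        for category in EXPECTED_CATEGORY_COUNTS:
            assert category in text
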