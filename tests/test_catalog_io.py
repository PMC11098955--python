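"""Catalog/table readers, writers, round-trips, and iTOL export."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from peplandscape import catalog_io
from peplandscape.catalog_io import (
    AnnotationRecord,
    Lineage,
    ProteinCatalog,
    ProteinRecord,
    phylum_colors,
    read_annotation_table,
    read_identified_peptides,
    read_lineage_table,
    read_protein_fasta,
    read_protein_groups,
    write_annotation_table,
    write_identified_peptides,
    write_itol_datasets,
    write_lineage_table,
    write_protein_fasta,
    write_protein_groups,
)


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class TestProteinFasta:
    def test_multi_file_read_counts_genomes_and_proteins(self, tmp_path):
        f1 = tmp_path / "a.faa"
        f2 = tmp_path / "b.faa"
        _write_fasta(f1, [("G1_00001", "MKRAAA"), ("G1_00002", "CCCC"), ("G1_00003", "DDDD")])
        _write_fasta(f2, [("G2_00001", "EEEE"), ("G2_00002", "FFFF")])
        catalog = read_protein_fasta([f1, f2])
        assert catalog.genomes == {"G1", "G2"}
        assert len(catalog.proteins) == 5

    def test_duplicate_protein_id_rejected(self, tmp_path):
        f = tmp_path / "dup.faa"
        _write_fasta(f, [("G1_00001", "AAAA"), ("G1_00001", "CCCC")])
        with pytest.raises(ValueError, match="G1_00001"):
            read_protein_fasta([f])

    def test_lowercase_sequence_normalized(self, tmp_path):
        f = tmp_path / "lc.faa"
        _write_fasta(f, [("G1_00001", "mkr")])
        catalog = read_protein_fasta([f])
        assert catalog.proteins[0].sequence == "MKR"

    def test_unparsable_header_names_record(self, tmp_path):
        f = tmp_path / "bad.faa"
        _write_fasta(f, [("noindexhere", "AAAA")])
        with pytest.raises(ValueError, match="noindexhere"):
            read_protein_fasta([f])

    def test_empty_file_warns_and_yields_empty_catalog(self, tmp_path):
        f = tmp_path / "empty.faa"
        f.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            catalog = read_protein_fasta([f])
        assert len(catalog.proteins) == 0

    def test_description_after_whitespace_ignored(self, tmp_path):
        f = tmp_path / "desc.faa"
        f.write_text(">G1_00001 hypothetical protein\nAAAA\n")
        catalog = read_protein_fasta([f])
        assert catalog.proteins[0].protein_id == "G1_00001"

    def test_wrapped_fasta_round_trip(self, tmp_path):
        catalog = ProteinCatalog([ProteinRecord("G1_00001", "G1", "ACDEFGHIKLMNPQRSTVWY" * 7)])
        out = tmp_path / "rt.faa"
        write_protein_fasta(catalog, out, wrap=60)
        back = read_protein_fasta([out])
        assert back.proteins[0].sequence == catalog.proteins[0].sequence


class TestLineageTable:
    LINE = "d__Bacteria;p__P1;c__C1;o__O1;f__F1;g__Gen1;s__Sp1"

    def test_parse_genus(self, tmp_path):
        f = tmp_path / "lin.tsv"
        f.write_text(f"genome\tlineage\nG1\t{self.LINE}\n")
        lineages = read_lineage_table(f)
        assert lineages["G1"].name_at("genus") == "Gen1"
        assert lineages["G1"].species == "Sp1"

    def test_six_rank_string_rejected(self, tmp_path):
        f = tmp_path / "lin.tsv"
        f.write_text("genome\tlineage\nG1\td__B;p__P;c__C;o__O;f__F;g__G\n")
        with pytest.raises(ValueError, match="rank ladder incomplete"):
            read_lineage_table(f)

    def test_empty_table_gives_empty_map(self, tmp_path):
        f = tmp_path / "lin.tsv"
        f.write_text("genome\tlineage\n")
        assert read_lineage_table(f) == {}

    def test_duplicate_genome_rejected(self, tmp_path):
        f = tmp_path / "lin.tsv"
        f.write_text(f"genome\tlineage\nG1\t{self.LINE}\nG1\t{self.LINE}\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_lineage_table(f)

    def test_missing_species_name_rejected(self, tmp_path):
        f = tmp_path / "lin.tsv"
        f.write_text("genome\tlineage\nG1\td__B;p__P;c__C;o__O;f__F;g__G;s__\n")
        with pytest.raises(ValueError, match="empty taxon name"):
            read_lineage_table(f)

    def test_unknown_rank_prefix_rejected(self, tmp_path):
        f = tmp_path / "lin.tsv"
        f.write_text("genome\tlineage\nG1\tx__B;p__P;c__C;o__O;f__F;g__G;s__S\n")
        with pytest.raises(ValueError, match="rank prefix"):
            read_lineage_table(f)

    def test_round_trip(self, tmp_path):
        lineages = {"G1": Lineage.from_string(self.LINE)}
        out = tmp_path / "rt.tsv"
        write_lineage_table(lineages, out)
        assert read_lineage_table(out) == lineages


class TestAnnotationTable:
    def test_full_record(self, tmp_path):
        f = tmp_path / "ann.tsv"
        f.write_text("protein\tcog\tcats\tko\tgo\nG1_00001\tCOG0001\tE\tko:K00001\tGO:0008150\n")
        rec = read_annotation_table(f)["G1_00001"]
        assert rec.cog_family == "COG0001"
        assert rec.cog_categories == frozenset("E")
        assert rec.kegg_ko == frozenset({"ko:K00001"})
        assert rec.go_terms == frozenset({"GO:0008150"})

    def test_all_absent_fields(self, tmp_path):
        f = tmp_path / "ann.tsv"
        f.write_text("protein\tcog\tcats\tko\tgo\nG1_00001\t-\t-\t-\t-\n")
        rec = read_annotation_table(f)["G1_00001"]
        assert rec.cog_family is None
        assert rec.cog_categories == frozenset()
        assert rec.kegg_ko == frozenset()
        assert rec.go_terms == frozenset()

    def test_multi_letter_categories_split(self, tmp_path):
        f = tmp_path / "ann.tsv"
        f.write_text("protein\tcog\tcats\tko\tgo\nG1_00001\tCOG0001\tES\t-\t-\n")
        rec = read_annotation_table(f)["G1_00001"]
        assert rec.cog_categories == frozenset({"E", "S"})

    def test_superset_of_catalog_warns_but_keeps(self, tmp_path, tiny_catalog):
        f = tmp_path / "ann.tsv"
        f.write_text("protein\tcog\tcats\tko\tgo\nNOT_IN_CATALOG_1\tCOG1\tE\t-\t-\n")
        with pytest.warns(UserWarning, match="not in catalog"):
            records = read_annotation_table(f, tiny_catalog)
        assert "NOT_IN_CATALOG_1" in records

    def test_round_trip(self, tmp_path):
        records = {
            "G1_00001": AnnotationRecord("G1_00001", "COG0001", frozenset("ES"),
                                         frozenset({"ko:K1", "ko:K2"}), frozenset({"GO:1"})),
            "G1_00002": AnnotationRecord("G1_00002"),
        }
        out = tmp_path / "rt.tsv"
        write_annotation_table(records, out)
        assert read_annotation_table(out) == records


class TestIdentificationTables:
    def test_identified_peptides_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"peptide": ["AAAAAAAK", "CCCCCCCR"], "study": ["S1", "S2"],
             "intensity": [1234.5, np.nan]}
        )
        out = tmp_path / "pep.tsv"
        write_identified_peptides(df, out)
        back = read_identified_peptides(out)
        pd.testing.assert_frame_equal(back, df)

    def test_within_study_duplicates_collapsed(self, tmp_path):
        f = tmp_path / "pep.tsv"
        f.write_text("peptide\tstudy\tintensity\nAAAAAAAK\tS1\t10\nAAAAAAAK\tS1\t5\nAAAAAAAK\tS2\t1\n")
        df = read_identified_peptides(f)
        assert len(df) == 2
        s1 = df[df["study"] == "S1"]["intensity"].iloc[0]
        assert s1 == 15

    def test_invalid_peptide_sequence_rejected(self, tmp_path):
        f = tmp_path / "pep.tsv"
        f.write_text("peptide\tstudy\tintensity\nAAA8AAAK\tS1\t10\n")
        with pytest.raises(ValueError, match="invalid peptide"):
            read_identified_peptides(f)

    def test_protein_groups_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"study": ["S1", "S1"], "members": [("A", "B"), ("C",)], "intensity": [10.0, np.nan]}
        )
        out = tmp_path / "grp.tsv"
        write_protein_groups(df, out)
        back = read_protein_groups(out)
        pd.testing.assert_frame_equal(back, df)


class TestItolExport:
    def _report(self):
        return pd.DataFrame(
            {
                "genome_distinct": [5, 0, 2],
                "genus_lca": [1, 1, 0],
                "family_lca": [0, 0, 3],
                "phylum": ["P1", "P1", "P2"],
            },
            index=["Sp1", "Sp2", "Sp3"],
        )

    def test_bar_dataset_has_data_lines_in_leaf_order(self, tmp_path):
        paths = write_itol_datasets(self._report(), ["Sp3", "Sp1", "Sp2"], tmp_path)
        lines = paths["multibar"].read_text().splitlines()
        assert lines[0] == "DATASET_MULTIBAR"
        data = lines[lines.index("DATA") + 1 :]
        assert [l.split(",")[0] for l in data] == ["Sp3", "Sp1", "Sp2"]
        assert data[1] == "Sp1,5,1,0"

    def test_same_phylum_same_strip_color(self, tmp_path):
        paths = write_itol_datasets(self._report(), ["Sp1", "Sp2", "Sp3"], tmp_path)
        lines = paths["colorstrip"].read_text().splitlines()
        data = {l.split(",")[0]: l.split(",")[1] for l in lines[lines.index("DATA") + 1 :]}
        assert data["Sp1"] == data["Sp2"]
        assert data["Sp1"] != data["Sp3"]

    def test_missing_leaf_listed_not_dropped(self, tmp_path):
        paths = write_itol_datasets(self._report(), ["Sp1", "Sp2"], tmp_path)
        assert paths["skipped"] == ["Sp3"]

    def test_empty_report_header_only_with_warning(self, tmp_path):
        empty = self._report().iloc[0:0]
        with pytest.warns(UserWarning, match="empty report"):
            paths = write_itol_datasets(empty, ["Sp1"], tmp_path)
        lines = paths["multibar"].read_text().splitlines()
        assert lines[-1] == "DATA"

    def test_phylum_palette_deterministic(self):
        assert phylum_colors(["B", "A"]) == phylum_colors(["A", "B", "A"])


def test_absence_is_never_empty_string(tmp_path):
    """Writers emit '-' markers; readers return explicit absent values."""
    records = {"G1_00001": AnnotationRecord("G1_00001")}
    out = tmp_path / "ann.tsv"
    write_annotation_table(records, out)
    body = out.read_text().splitlines()[1]
    assert body.split("\t")[1:] == ["-", "-", "-", "-"]
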