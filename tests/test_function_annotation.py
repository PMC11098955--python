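"""Annotation-coverage accounting and COG-family peptide distinctness."""

from __future__ import annotations

import pandas as pd
import pytest

from peplandscape.catalog_io import AnnotationRecord
from peplandscape.digestion import DigestionParams
from peplandscape.function_annotation import (
    annotation_summary,
    functional_distinctness,
    has_ko_or_go,
    high_abundance_unannotated,
    is_cog_unknown,
    species_annotation_ratio,
)
from peplandscape.taxa_assign import PeptideOccurrenceIndex, build_index
from peplandscape.coverage import head_protein_extraction


def _rec(pid, fam=None, cats="", ko=(), go=()):
    return AnnotationRecord(pid, fam, frozenset(cats), frozenset(ko), frozenset(go))


class TestAnnotationRules:
    def test_broad_rule_needs_ko_or_go(self):
        assert not has_ko_or_go(_rec("p"))
        assert has_ko_or_go(_rec("p", ko=("ko:K1",)))
        assert has_ko_or_go(_rec("p", go=("GO:1",)))
        assert not has_ko_or_go(None)

    def test_strict_rule_no_family_or_only_s(self):
        assert is_cog_unknown(_rec("p"))
        assert is_cog_unknown(_rec("p", fam="COGX", cats="S"))
        assert not is_cog_unknown(_rec("p", fam="COGX", cats="ES"))
        assert not is_cog_unknown(_rec("p", fam="COGX", cats="E"))
        assert is_cog_unknown(None)


class TestAnnotationSummary:
    def test_counts_and_percentages(self):
        annotations = {
            "a": _rec("a", fam="COG1", cats="E", ko=("ko:K1",)),
            "b": _rec("b"),                       # broad-missing + strict-unknown
            "c": _rec("c", fam="COG2", cats="S", ko=("ko:K2",)),  # strict-unknown only
        }
        s = annotation_summary({"a", "b", "c"}, annotations)
        assert (s.n_total, s.n_no_ko_go, s.n_cog_unknown) == (3, 1, 2)
        assert s.pct_no_ko_go == 33.3
        assert s.pct_cog_unknown == 66.67

    def test_missing_record_treated_as_unannotated(self):
        s = annotation_summary({"ghost"}, {})
        assert (s.n_no_ko_go, s.n_cog_unknown) == (1, 1)

    def test_all_annotated_gives_zeroes(self):
        annotations = {"a": _rec("a", fam="COG1", cats="E", ko=("ko:K1",))}
        s = annotation_summary({"a"}, annotations)
        assert (s.n_no_ko_go, s.pct_no_ko_go, s.n_cog_unknown, s.pct_cog_unknown) == (0, 0.0, 0, 0.0)


class TestHighAbundance:
    def _groups(self, intensities, study="S1"):
        return pd.DataFrame(
            {
                "study": [study] * len(intensities),
                "members": [(f"p{i}",) for i in range(len(intensities))],
                "intensity": intensities,
            }
        )

    def test_top_decile_of_ten_is_exactly_one(self):
        groups = self._groups([float(i) for i in range(10)])
        annotations = {f"p{i}": _rec(f"p{i}") for i in range(10)}  # all unannotated
        n, table = high_abundance_unannotated(groups, annotations, decile=0.10)
        assert n == 1
        assert table["protein"].tolist() == ["p9"]  # the single top-intensity protein

    def test_no_unannotated_proteins_counts_zero(self):
        groups = self._groups([1.0, 2.0, 3.0])
        annotations = {f"p{i}": _rec(f"p{i}", fam="COG1", cats="E") for i in range(3)}
        n, _ = high_abundance_unannotated(groups, annotations)
        assert n == 0

    def test_intensity_summed_across_groups_within_study(self):
        groups = pd.DataFrame(
            {
                "study": ["S1", "S1", "S1"],
                "members": [("a",), ("a",), ("b",)],
                "intensity": [5.0, 5.0, 8.0],
            }
        )
        annotations = {"a": _rec("a"), "b": _rec("b", fam="COG1", cats="E")}
        n, table = high_abundance_unannotated(groups, annotations, decile=0.5)
        # a totals 10 > b's 8, so the top-1 slot goes to the unannotated a
        assert table["protein"].tolist() == ["a"]

    def test_qualifying_in_any_study_suffices(self):
        groups = pd.concat(
            [self._groups([1.0, 100.0], study="S1"), self._groups([100.0, 1.0], study="S2")]
        ).reset_index(drop=True)
        annotations = {"p0": _rec("p0"), "p1": _rec("p1")}
        n, _ = high_abundance_unannotated(groups, annotations, decile=0.5)
        assert n == 2

    def test_planted_high_intensity_unannotated_recovered(self, synth_bundle):
        """The simulator's ledger identifies unannotated proteins; the ones
        heading top-decile groups must be flagged."""
        groups = synth_bundle["groups"]
        annotations = synth_bundle["annotations"]
        n, table = high_abundance_unannotated(groups, annotations)
        assert set(table["protein"]) <= {
            p for p in annotations if is_cog_unknown(annotations[p])
        } | (synth_bundle["truth"].missing_proteins | synth_bundle["truth"].cog_s_proteins)
        assert n == len(table)


class TestSpeciesAnnotationRatio:
    def test_threshold_excludes_small_species(self, tiny_catalog):
        heads = {"G1_00001", "G1_00002"}
        annotations = {h: _rec(h, fam="COG1", cats="E") for h in heads}
        table = species_annotation_ratio(heads, annotations, tiny_catalog, min_proteins=100)
        assert table.empty
        table2 = species_annotation_ratio(heads, annotations, tiny_catalog, min_proteins=2)
        assert table2["species"].tolist() == ["Sp1"]
        assert table2["annotated_pct"].iloc[0] == 100.0

    def test_fraction_matches_ledger_on_synthetic(self, synth_bundle):
        catalog = synth_bundle["catalog"]
        annotations = synth_bundle["annotations"]
        truth = synth_bundle["truth"]
        heads, _ = head_protein_extraction(synth_bundle["groups"])
        table = species_annotation_ratio(heads, annotations, catalog, min_proteins=10)
        unknown = truth.missing_proteins | truth.cog_s_proteins
        protein_species = {p.protein_id: catalog.species_of(p.genome_id) for p in catalog.proteins}
        for _, row in table.iterrows():
            sp_heads = [h for h in heads if protein_species.get(h) == row["species"]]
            expected = sum(1 for h in sp_heads if h not in unknown)
            assert row["n_annotated"] == expected


class TestFunctionalDistinctness:
    def _index(self, mapping):
        params = DigestionParams()
        return PeptideOccurrenceIndex(
            proteins={k: frozenset(v) for k, v in mapping.items()},
            genomes={k: frozenset() for k in mapping},
            params=params,
        )

    def test_unique_families_no_sharing_is_all_distinct(self):
        index = self._index({"PEPA": ["a"], "PEPB": ["b"]})
        annotations = {"a": _rec("a", fam="COG1", cats="E"), "b": _rec("b", fam="COG2", cats="F")}
        classes = functional_distinctness(index, annotations)
        assert classes.n_functional_distinct == 2
        assert classes.fractions["functional_distinct"] == 100.0

    def test_three_way_classification(self):
        index = self._index(
            {"P1": ["a"], "P2": ["u"], "P3": ["a", "b"], "P4": ["a", "u"]}
        )
        annotations = {
            "a": _rec("a", fam="COG1", cats="E"),
            "b": _rec("b", fam="COG2", cats="F"),
            "u": _rec("u"),
        }
        classes = functional_distinctness(index, annotations)
        assert classes.n_functional_distinct == 2  # P1 and the mixed P4
        assert classes.n_unannotated_distinct == 1
        assert classes.n_shared_multi_family == 1
        assert classes.n_mixed_family_unannotated == 1

    def test_partition_identity_on_synthetic(self, synth_bundle):
        index = build_index(synth_bundle["catalog"])
        classes = functional_distinctness(index, synth_bundle["annotations"])
        total = (
            classes.n_functional_distinct
            + classes.n_unannotated_distinct
            + classes.n_shared_multi_family
        )
        assert total == classes.n_total_unique == len(index)
        assert abs(sum(classes.fractions.values()) - 100.0) < 1e-9

    def test_classes_match_ledger_recomputation(self, synth_bundle):
        """Brute-force recomputation from the ledger's family map agrees."""
        catalog = synth_bundle["catalog"]
        truth = synth_bundle["truth"]
        index = build_index(catalog)
        classes = functional_distinctness(index, synth_bundle["annotations"])
        n_func = n_unannot = n_shared = 0
        for pep, proteins in index.proteins.items():
            fams = {truth.family_of[p] for p in proteins if p in truth.family_of}
            if not fams:
                n_unannot += 1
            elif len(fams) == 1:
                n_func += 1
            else:
                n_shared += 1
        assert (classes.n_functional_distinct, classes.n_unannotated_distinct,
                classes.n_shared_multi_family) == (n_func, n_unannot, n_shared)
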