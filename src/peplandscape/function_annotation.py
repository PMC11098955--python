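"""Annotation-coverage accounting and COG-family peptide distinctness.

Two annotation rules are tracked side by side and never merged:

* broad-missing: a protein has neither a KEGG ko nor a GO term;
* strict COG-unknown: a protein has no COG family, or its categories
  are exactly {S} ("Function unknown").

The peptide-space classification asks, for every unique catalog
peptide, which COG families its source proteins belong to: exactly one
family → functional-distinct; no family anywhere → unannotated-
distinct; two or more families → shared-multi-family. A peptide seen in
one family plus unannotated proteins counts as functional-distinct to
that family (any family evidence wins); these mixed cases are reported
separately for transparency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .catalog_io import AnnotationRecord, ProteinCatalog
from .reporting import format_percent, percent_split
from .taxa_assign import PeptideOccurrenceIndex

logger = logging.getLogger(__name__)


def has_ko_or_go(record: AnnotationRecord | None) -> bool:
    if record is None:
        return False
    return bool(record.kegg_ko) or bool(record.go_terms)


def is_cog_unknown(record: AnnotationRecord | None) -> bool:
    """No COG family, or assigned only to category S (Function unknown)."""
    if record is None:
        return True
    return record.cog_family is None or record.cog_categories == frozenset("S")


@dataclass
class AnnotationSummary:
    n_total: int
    n_no_ko_go: int
    n_cog_unknown: int

    @property
    def pct_no_ko_go(self) -> float:
        return float("nan") if self.n_total == 0 else format_percent(self.n_no_ko_go, self.n_total, 1)

    @property
    def pct_cog_unknown(self) -> float:
        return float("nan") if self.n_total == 0 else format_percent(self.n_cog_unknown, self.n_total, 2)


def annotation_summary(
    head_set: set[str], annotations: Mapping[str, AnnotationRecord]
) -> AnnotationSummary:
    """Broad-missing and strict COG-unknown counts over the head set.

    A head protein without an annotation record is treated as fully
    unannotated (logged).
    """
    missing_records = sum(1 for h in head_set if h not in annotations)
    if missing_records:
        logger.info("%d head proteins lack annotation records: treated as unannotated", missing_records)
    n_no = sum(1 for h in head_set if not has_ko_or_go(annotations.get(h)))
    n_unknown = sum(1 for h in head_set if is_cog_unknown(annotations.get(h)))
    if not head_set:
        return AnnotationSummary(0, 0, 0)
    return AnnotationSummary(len(head_set), n_no, n_unknown)


def protein_study_intensities(groups: pd.DataFrame) -> pd.DataFrame:
    """Total intensity of each head protein per study.

    A protein's total intensity within a study is the sum of the
    intensities of the groups it heads in that study.
    """
    rows = []
    for study, members, intensity in zip(groups["study"], groups["members"], groups["intensity"]):
        if not pd.isna(intensity):
            rows.append({"study": study, "protein": members[0], "intensity": float(intensity)})
    if not rows:
        return pd.DataFrame(columns=["study", "protein", "intensity"])
    df = pd.DataFrame(rows)
    return df.groupby(["study", "protein"], as_index=False)["intensity"].sum()


def high_abundance_unannotated(
    groups: pd.DataFrame,
    annotations: Mapping[str, AnnotationRecord],
    decile: float = 0.10,
) -> tuple[int, pd.DataFrame]:
    """COG-unknown head proteins within the intensity top decile of any study.

    Per study, proteins are ranked by total intensity descending and the
    top ``ceil(decile * n_study_proteins)`` qualify as highly abundant.
    Returns the count of highly abundant COG-unknown proteins plus the
    protein list with the studies in which each qualified.
    """
    intens = protein_study_intensities(groups)
    qualifying: dict[str, set[str]] = {}
    for study, sub in intens.groupby("study"):
        if sub.empty:
            logger.warning("study %s has no intensities: skipped", study)
            continue
        k = math.ceil(decile * len(sub))
        top = sub.sort_values(["intensity", "protein"], ascending=[False, True]).head(k)
        for prot in top["protein"]:
            qualifying.setdefault(prot, set()).add(str(study))
    hits = sorted(p for p in qualifying if is_cog_unknown(annotations.get(p)))
    table = pd.DataFrame(
        {"protein": hits, "studies": [",".join(sorted(qualifying[p])) for p in hits]}
    )
    return len(hits), table


def species_annotation_ratio(
    head_set: set[str],
    annotations: Mapping[str, AnnotationRecord],
    catalog: ProteinCatalog,
    min_proteins: int = 100,
) -> pd.DataFrame:
    """Per-species annotated fraction (strict rule) for well-covered species.

    Only species with at least ``min_proteins`` identified head proteins
    are reported; "annotated" means not strict COG-unknown.
    """
    protein_index = catalog.protein_index()
    per_species: dict[str, list[str]] = {}
    for head in head_set:
        rec = protein_index.get(head)
        if rec is None:
            continue
        per_species.setdefault(catalog.species_of(rec.genome_id), []).append(head)
    rows = []
    for species in sorted(per_species):
        heads = per_species[species]
        if len(heads) < min_proteins:
            continue
        n_annot = sum(1 for h in heads if not is_cog_unknown(annotations.get(h)))
        rows.append(
            {
                "species": species,
                "n_head_proteins": len(heads),
                "n_annotated": n_annot,
                "annotated_pct": format_percent(n_annot, len(heads), 1),
            }
        )
    return pd.DataFrame(rows, columns=["species", "n_head_proteins", "n_annotated", "annotated_pct"])


@dataclass
class FunctionalPeptideClasses:
    """Partition of the unique catalog peptide space by COG-family evidence."""

    n_total_unique: int
    n_total_redundant: int
    n_functional_distinct: int
    n_unannotated_distinct: int
    n_shared_multi_family: int
    n_mixed_family_unannotated: int  # subset of functional_distinct, logged separately

    @property
    def fractions(self) -> dict[str, float]:
        f, u, s = (
            self.n_functional_distinct,
            self.n_unannotated_distinct,
            self.n_shared_multi_family,
        )
        pf, pu, ps = percent_split([f, u, s], 1)
        return {"functional_distinct": pf, "unannotated_distinct": pu, "shared_multi_family": ps}

    def __post_init__(self) -> None:
        parts = self.n_functional_distinct + self.n_unannotated_distinct + self.n_shared_multi_family
        if parts != self.n_total_unique:
            raise ValueError(
                f"peptide classes do not partition the unique peptide set: {parts} != {self.n_total_unique}"
            )


def functional_distinctness(
    index: PeptideOccurrenceIndex,
    annotations: Mapping[str, AnnotationRecord],
    n_total_redundant: int | None = None,
) -> FunctionalPeptideClasses:
    """Classify every unique catalog peptide by its source COG families."""
    n_func = n_unannot = n_shared = n_mixed = 0
    for pep, proteins in index.proteins.items():
        families: set[str] = set()
        any_unannotated = False
        for pid in proteins:
            rec = annotations.get(pid)
            if rec is not None and rec.cog_family is not None:
                families.add(rec.cog_family)
            else:
                any_unannotated = True
        if len(families) == 0:
            n_unannot += 1
        elif len(families) == 1:
            n_func += 1
            if any_unannotated:
                n_mixed += 1
        else:
            n_shared += 1
    return FunctionalPeptideClasses(
        n_total_unique=len(index.proteins),
        n_total_redundant=n_total_redundant if n_total_redundant is not None else len(index.proteins),
        n_functional_distinct=n_func,
        n_unannotated_distinct=n_unannot,
        n_shared_multi_family=n_shared,
        n_mixed_family_unannotated=n_mixed,
    )
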