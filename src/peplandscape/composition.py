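"""Rank-level taxonomic composition: catalog genomes vs identified peptides.

Two views of the same community are compared at each rank: the fraction
of catalog species per taxon (the metagenomics reference view) and the
fraction of identified peptides per taxon (the metaproteomics view). A
peptide contributes to taxon T at rank r iff its LCA is at rank r or
deeper and its shared lineage at r is T; the denominator at rank r is
therefore the peptides assignable at r or deeper, so fractions within a
rank always sum to 1. The top-N overlap statistic counts taxa shared
between the most genome-rich and most peptide-rich taxa at a rank.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd

from .catalog_io import RANK_DEPTH, ProteinCatalog
from .taxa_assign import PeptideAssignment


def reference_composition(catalog: ProteinCatalog, rank: str) -> pd.DataFrame:
    """Catalog-side composition: species counted per taxon at ``rank``."""
    depth = RANK_DEPTH[rank]
    counts: dict[str, int] = {}
    for genome in catalog.genomes:
        taxon = catalog.lineages[genome].names[depth]
        counts[taxon] = counts.get(taxon, 0) + 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "rank": rank,
            "taxon": sorted(counts),
            "count": [counts[t] for t in sorted(counts)],
            "fraction": [counts[t] / total for t in sorted(counts)],
            "denominator": "catalog-species",
        }
    )


def peptide_composition(
    assignments: Mapping[str, PeptideAssignment], rank: str
) -> pd.DataFrame:
    """Peptide-side composition at ``rank`` (rank-assignable denominator).

    Peptides whose LCA is shallower than ``rank`` are excluded from the
    denominator; the excluded count is carried in the ``n_excluded``
    attribute column for inspection of the alternative all-peptides
    denominator.
    """
    depth = RANK_DEPTH[rank]
    counts: dict[str, int] = {}
    excluded = 0
    for a in assignments.values():
        if len(a.lineage_prefix) > depth:
            taxon = a.lineage_prefix[depth]
            counts[taxon] = counts.get(taxon, 0) + 1
        else:
            excluded += 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "rank": rank,
            "taxon": sorted(counts),
            "count": [counts[t] for t in sorted(counts)],
            "fraction": [counts[t] / total for t in sorted(counts)] if total else [],
            "denominator": "rank-assignable-peptides",
        }
    )
    df.attrs["n_excluded"] = excluded
    df.attrs["n_assignable"] = total
    return df


def top_taxa(composition: pd.DataFrame, n: int) -> list[str]:
    """Top-n taxa by count; boundary ties broken by taxon name."""
    ordered = composition.sort_values(["count", "taxon"], ascending=[False, True])
    return list(ordered["taxon"].head(n))


def top_overlap(
    comp_a: pd.DataFrame, comp_b: pd.DataFrame, n: int
) -> tuple[int, list[str], list[str]]:
    """Overlap between the top-n taxa of two same-rank compositions."""
    ranks_a = set(comp_a["rank"].unique())
    ranks_b = set(comp_b["rank"].unique())
    if ranks_a and ranks_b and ranks_a != ranks_b:
        raise ValueError(f"compositions are at different ranks: {ranks_a} vs {ranks_b}")
    if n > max(len(comp_a), len(comp_b)):
        warnings.warn(f"n={n} exceeds taxon count: using all taxa", stacklevel=2)
    list_a = top_taxa(comp_a, n)
    list_b = top_taxa(comp_b, n)
    return len(set(list_a) & set(list_b)), list_a, list_b
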