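"""Peptide- and protein-level proteome coverage per species.

Peptide-level coverage of a species is the fraction of its in-silico
tryptic peptide universe observed among the identified peptides; the
numerator includes peptides assigned to higher-rank LCAs whenever their
sequence occurs in the species' universe. Protein-level coverage is the
fraction of the representative genome's CDS observed as head proteins
of identified protein groups. Protein coverage is summarised into the
bins <5%, 5-10%, 10-20%, 20-50%, >=50% (left-closed, right-open except
the last), which partition [0, 1] exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .catalog_io import ProteinCatalog
from .reporting import format_percent
from .taxa_assign import PeptideOccurrenceIndex

logger = logging.getLogger(__name__)

COVERAGE_BINS: tuple[tuple[float, float, str], ...] = (
    (0.00, 0.05, "<5%"),
    (0.05, 0.10, "5-10%"),
    (0.10, 0.20, "10-20%"),
    (0.20, 0.50, "20-50%"),
    (0.50, math.inf, ">=50%"),
)


def coverage_bin(fraction: float) -> str:
    """Bin label for a coverage fraction in [0, 1]."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"coverage fraction out of [0,1]: {fraction}")
    for lo, hi, label in COVERAGE_BINS:
        if lo <= fraction < hi:
            return label
    return COVERAGE_BINS[-1][2]  # fraction == 1.0 lands in the open-ended bin


def peptide_coverage(
    retained_peptides: Iterable[str],
    index: PeptideOccurrenceIndex,
    per_genome_sets: Mapping[str, set[str]],
    catalog: ProteinCatalog,
) -> pd.DataFrame:
    """Per-species identified/in-silico peptide counts and coverage.

    ``retained_peptides`` are the unique identified peptides that survived
    host filtering (microbial + shared). A peptide counts toward every
    species whose in-silico set contains it, so peptides with genus- or
    family-level LCAs still contribute to each member species.
    """
    occurring: dict[str, int] = {g: 0 for g in catalog.genomes}
    for pep in set(index.params.key(p) for p in retained_peptides):
        for g in index.genomes_of(pep):
            occurring[g] += 1
    rows = []
    for genome in sorted(catalog.genomes):
        total = len(per_genome_sets.get(genome, set()))
        n = occurring[genome]
        if total == 0:
            logger.warning("genome %s has an empty in-silico peptide set", genome)
            frac, pct = float("nan"), float("nan")
        else:
            frac = n / total
            pct = format_percent(n, total, 2)
        rows.append(
            {
                "genome": genome,
                "species": catalog.species_of(genome),
                "occurring_identified_peptides": n,
                "total_insilico_peptides": total,
                "peptide_coverage_fraction": frac,
                "peptide_coverage_pct": pct,
            }
        )
    return pd.DataFrame(rows)


def head_protein_extraction(groups: pd.DataFrame) -> tuple[set[str], pd.DataFrame]:
    """Unique head proteins (first-listed group member) across all studies.

    Returns the head set plus a provenance table mapping each head to the
    studies it appeared in.
    """
    prov: dict[str, set[str]] = {}
    for study, members in zip(groups["study"], groups["members"]):
        if not members:
            raise ValueError("empty protein-group member list")
        prov.setdefault(members[0], set()).add(study)
    table = pd.DataFrame(
        {
            "head_protein": sorted(prov),
            "studies": [",".join(sorted(prov[h])) for h in sorted(prov)],
        }
    )
    return set(prov), table


def protein_coverage(
    head_set: set[str], catalog: ProteinCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species head-protein counts over CDS, plus a bin summary.

    Head proteins absent from the catalog are kept in the head set by the
    caller but excluded from species attribution here (logged).
    """
    protein_index = catalog.protein_index()
    per_genome: dict[str, int] = {g: 0 for g in catalog.genomes}
    missing = 0
    for head in head_set:
        rec = protein_index.get(head)
        if rec is None:
            missing += 1
            continue
        per_genome[rec.genome_id] += 1
    if missing:
        logger.info("%d head proteins not in catalog: excluded from species attribution", missing)
    cds = catalog.cds_counts()
    rows = []
    for genome in sorted(catalog.genomes):
        n, total = per_genome[genome], cds[genome]
        frac = n / total
        rows.append(
            {
                "genome": genome,
                "species": catalog.species_of(genome),
                "identified_head_proteins": n,
                "cds_count": total,
                "protein_coverage_fraction": frac,
                "protein_coverage_pct": format_percent(n, total, 1),
                "coverage_bin": coverage_bin(frac),
            }
        )
    table = pd.DataFrame(rows)
    labels = [b[2] for b in COVERAGE_BINS]
    bin_counts = table["coverage_bin"].value_counts()
    summary = pd.DataFrame(
        {"coverage_bin": labels, "n_species": [int(bin_counts.get(l, 0)) for l in labels]}
    )
    return table, summary


@dataclass
class SparseSpeciesReport:
    n_sparse: int
    n_zero: int
    family_contributors: pd.DataFrame
    genus_contributors: pd.DataFrame


def sparse_species_report(
    distinct_counts: pd.DataFrame, threshold: float = 5
) -> SparseSpeciesReport:
    """Species with few (<= threshold) genome-distinct peptides.

    ``distinct_counts`` is the species table from
    :func:`peplandscape.taxa_assign.genome_distinct_counts` (zero rows
    included). Contributor tables rank families/genera by their number of
    sparse species, count-descending with name as the deterministic
    tie-break.
    """
    sparse = distinct_counts[distinct_counts["genome_distinct"] <= threshold]
    n_zero = int((distinct_counts["genome_distinct"] == 0).sum())

    def contributors(rank_col: str) -> pd.DataFrame:
        if sparse.empty:
            return pd.DataFrame(columns=[rank_col, "n_sparse_species"])
        counts = sparse.groupby(rank_col).size().reset_index(name="n_sparse_species")
        return counts.sort_values(
            ["n_sparse_species", rank_col], ascending=[False, True]
        ).reset_index(drop=True)

    return SparseSpeciesReport(
        n_sparse=len(sparse),
        n_zero=n_zero,
        family_contributors=contributors("family"),
        genus_contributors=contributors("genus"),
    )
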