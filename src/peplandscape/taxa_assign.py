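"""Peptide occurrence index, host-peptide filtering, and LCA assignment.

A peptide found in exactly one representative genome is genome-distinct
and is assigned at species rank; a peptide shared by several genomes is
assigned to the deepest rank at which all of its source genomes carry
the same taxon name (the lowest common ancestor on the fixed 7-rank
ladder). Peptides found exclusively in the host proteome are excluded
from all microbial statistics; peptides found in both host and catalog
are retained and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .catalog_io import RANKS, Lineage, ProteinCatalog
from .digestion import DigestionParams, digest_sequence

logger = logging.getLogger(__name__)


class PeptideStatus(str, Enum):
    HOST_ONLY = "host_only"
    SHARED_HOST_MICROBIAL = "shared_host_microbial"
    MICROBIAL = "microbial"
    UNMAPPED = "unmapped"  # in neither catalog nor host


@dataclass
class PeptideOccurrenceIndex:
    """Inverted index: peptide key → (source proteins, source genomes)."""

    proteins: dict[str, frozenset[str]]
    genomes: dict[str, frozenset[str]]
    params: DigestionParams

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, peptide: str) -> bool:
        return self.params.key(peptide) in self.proteins

    def genomes_of(self, peptide: str) -> frozenset[str]:
        return self.genomes.get(self.params.key(peptide), frozenset())

    def proteins_of(self, peptide: str) -> frozenset[str]:
        return self.proteins.get(self.params.key(peptide), frozenset())

    def per_genome_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for pep, gset in self.genomes.items():
            for g in gset:
                out.setdefault(g, set()).add(pep)
        return out


def build_index(catalog: ProteinCatalog, params: DigestionParams = DigestionParams()) -> PeptideOccurrenceIndex:
    """Digest every catalog protein and build the exact inverted index."""
    prot_map: dict[str, set[str]] = {}
    gen_map: dict[str, set[str]] = {}
    for p in catalog.proteins:
        for pep in digest_sequence(p.sequence, params, p.protein_id):
            key = params.key(pep.sequence)
            prot_map.setdefault(key, set()).add(p.protein_id)
            gen_map.setdefault(key, set()).add(p.genome_id)
    return PeptideOccurrenceIndex(
        proteins={k: frozenset(v) for k, v in prot_map.items()},
        genomes={k: frozenset(v) for k, v in gen_map.items()},
        params=params,
    )


@dataclass
class HostPartition:
    host_only: set[str]
    shared_host_microbial: set[str]
    microbial: set[str]
    unmapped: set[str]

    @property
    def overlap_count(self) -> int:
        """Peptides found in both the host and the microbial catalog."""
        return len(self.shared_host_microbial)

    @property
    def retained(self) -> set[str]:
        """Peptides entering microbial statistics (shared kept, host-only out)."""
        return self.microbial | self.shared_host_microbial

    def status_of(self, peptide_key: str) -> PeptideStatus:
        if peptide_key in self.host_only:
            return PeptideStatus.HOST_ONLY
        if peptide_key in self.shared_host_microbial:
            return PeptideStatus.SHARED_HOST_MICROBIAL
        if peptide_key in self.microbial:
            return PeptideStatus.MICROBIAL
        return PeptideStatus.UNMAPPED


def partition_host(
    peptides: Iterable[str],
    host_peptides: set[str],
    index: PeptideOccurrenceIndex,
) -> HostPartition:
    """Split identified peptides by host/microbial provenance.

    ``host_peptides`` must come from digesting the host proteome with the
    same parameters as the catalog index. Input peptides are reduced to
    unique matching keys first.
    """
    part = HostPartition(set(), set(), set(), set())
    for pep in peptides:
        key = index.params.key(pep)
        in_host = key in host_peptides
        in_catalog = key in index.proteins
        if in_host and in_catalog:
            part.shared_host_microbial.add(key)
        elif in_host:
            part.host_only.add(key)
        elif in_catalog:
            part.microbial.add(key)
        else:
            part.unmapped.add(key)
    if part.unmapped:
        logger.info("%d peptides found in neither catalog nor host (unmapped)", len(part.unmapped))
    return part


@dataclass(frozen=True)
class PeptideAssignment:
    peptide: str
    status: PeptideStatus
    rank: str | None  # None = no shared rank (or host-only / unmapped)
    taxon: str | None
    genome_distinct: bool
    lineage_prefix: tuple[str, ...] = ()  # shared lineage names down to the LCA rank


def lca_prefix(lineages: Iterable[Lineage]) -> tuple[str, ...]:
    """Deepest common lineage prefix across genomes (may be empty)."""
    rows = [lin.names for lin in lineages]
    prefix: list[str] = []
    for names in zip(*rows):
        if all(n == names[0] for n in names):
            prefix.append(names[0])
        else:
            break
    return tuple(prefix)


def assign_lca(
    peptide: str,
    index: PeptideOccurrenceIndex,
    lineages: Mapping[str, Lineage],
    status: PeptideStatus = PeptideStatus.MICROBIAL,
) -> PeptideAssignment:
    """Assign one catalog peptide its genome-distinct or LCA label."""
    genomes = index.genomes_of(peptide)
    if not genomes:
        raise KeyError(f"peptide {peptide!r} not in index")
    key = index.params.key(peptide)
    prefix = lca_prefix(lineages[g] for g in genomes)
    if not prefix:
        logger.info("peptide %s spans domains: no shared rank", key)
        return PeptideAssignment(key, status, None, None, False, ())
    rank = RANKS[len(prefix) - 1]
    distinct = len(genomes) == 1
    return PeptideAssignment(key, status, rank, prefix[-1], distinct, prefix)


def assign_all(
    partition: HostPartition,
    index: PeptideOccurrenceIndex,
    lineages: Mapping[str, Lineage],
) -> dict[str, PeptideAssignment]:
    """Assignments for every retained (microbial or shared) peptide."""
    out: dict[str, PeptideAssignment] = {}
    for pep in sorted(partition.retained):
        out[pep] = assign_lca(pep, index, lineages, partition.status_of(pep))
    return out


def genome_distinct_counts(
    assignments: Mapping[str, PeptideAssignment],
    catalog: ProteinCatalog,
    bacteria_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species genome-distinct peptide counts and a per-rank tally.

    The species table has one row per catalog species, including explicit
    zeros. ``bacteria_only`` drops non-Bacteria genomes from the species
    table (the rank tally always covers the full assignment set).
    """
    counts: dict[str, int] = {}
    for a in assignments.values():
        if a.genome_distinct:
            counts[a.taxon] = counts.get(a.taxon, 0) + 1
    rows = []
    for genome in sorted(catalog.genomes):
        lin = catalog.lineages[genome]
        if bacteria_only and lin.name_at("domain") != "Bacteria":
            continue
        rows.append(
            {
                "genome": genome,
                "species": lin.species,
                "phylum": lin.name_at("phylum"),
                "genus": lin.name_at("genus"),
                "family": lin.name_at("family"),
                "genome_distinct": counts.get(lin.species, 0),
            }
        )
    species_table = pd.DataFrame(rows)

    tally: dict[str, int] = {r: 0 for r in RANKS}
    tally["no_shared_rank"] = 0
    for a in assignments.values():
        tally[a.rank if a.rank is not None else "no_shared_rank"] += 1
    rank_table = pd.DataFrame(
        {"rank": list(tally), "n_peptides": [tally[r] for r in tally]}
    )
    return species_table, rank_table
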