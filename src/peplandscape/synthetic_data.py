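"""Synthetic genome catalogs, annotations, and identification tables.

The generator emulates the shape of the real inputs — a ranked
multi-genome protein catalog with controlled inter-species sequence
sharing, an eggNOG-style annotation table with controlled missingness,
a host proteome, and per-study identified-peptide / protein-group
tables sampled with biased (Dirichlet) taxon abundance — while
recording a ground-truth ledger from which every downstream statistic
can be recomputed independently.

Sequence model: i.i.d. residues over the 20 standard amino acids with
K and R at 1/18 each (combined cleavage-residue probability 1/9, so the
mean tryptic fragment length is about 9 residues) and the remaining 18
residues uniform. Protein lengths are geometric around the configured
mean with a floor of 30 residues. Within each genus, a configurable
fraction of each species' proteome consists of ortholog copies of the
genus's first species, mutated at a per-residue substitution rate;
ortholog copies inherit the donor's COG family, so the functional-
distinctness ground truth is known by construction.

Identical seed and config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog_io import (
    Lineage,
    ProteinCatalog,
    ProteinRecord,
    write_annotation_table,
    write_identified_peptides,
    write_lineage_table,
    write_protein_fasta,
    write_protein_groups,
)
from .catalog_io import AnnotationRecord
from .digestion import DigestionParams, digest_peptide_pool
from .taxa_assign import build_index

RESIDUES = sorted("ACDEFGHIKLMNPQRSTVWY")
#: COG functional category letters excluding S (Function unknown)
COG_LETTERS = sorted(set("CDEFGHIJKLMNOPQTUVWZ") - {"S"})
UNKNOWN_FAMILY = "COGUNKN"  # dedicated unknown-function family, category S

# independent RNG streams per generation stage
_STREAM_CATALOG, _STREAM_HOST, _STREAM_ANNOT, _STREAM_IDENT = 11, 13, 17, 19


@dataclass(frozen=True)
class SynthesisConfig:
    seed: int = 1
    n_phyla: int = 3
    classes_per_phylum: int = 1
    orders_per_class: int = 1
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    proteins_per_genome: int = 100
    mean_protein_length: int = 300
    ortholog_share_rate: float = 0.2
    ortholog_mutation_rate: float = 0.02
    annotation_missing_rate: float = 0.25
    cog_s_rate: float = 0.09
    n_identified_peptides: int = 20_000
    abundance_skew: float = 0.3
    host_fraction: float = 0.05
    n_host_proteins: int = 200
    n_studies: int = 3

    def __post_init__(self) -> None:
        for name in (
            "ortholog_share_rate",
            "ortholog_mutation_rate",
            "annotation_missing_rate",
            "cog_s_rate",
            "host_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.annotation_missing_rate + self.cog_s_rate > 1:
            raise ValueError("annotation_missing_rate + cog_s_rate must be <= 1")
        for name in (
            "n_phyla",
            "classes_per_phylum",
            "orders_per_class",
            "families_per_order",
            "genera_per_family",
            "species_per_genus",
            "proteins_per_genome",
            "n_host_proteins",
            "n_studies",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"degenerate tree/config: {name} must be >= 1")
        if self.abundance_skew <= 0:
            raise ValueError("abundance_skew must be > 0")
        if self.mean_protein_length < 31:
            raise ValueError("mean_protein_length must exceed the 30-residue floor")

    @property
    def n_species(self) -> int:
        return (
            self.n_phyla
            * self.classes_per_phylum
            * self.orders_per_class
            * self.families_per_order
            * self.genera_per_family
            * self.species_per_genus
        )


@dataclass
class GroundTruth:
    """Everything needed to recompute downstream statistics independently."""

    config: SynthesisConfig
    ortholog_groups: dict[str, list[str]] = field(default_factory=dict)
    protein_ortholog: dict[str, str] = field(default_factory=dict)
    missing_proteins: set[str] = field(default_factory=set)
    cog_s_proteins: set[str] = field(default_factory=set)
    family_of: dict[str, str] = field(default_factory=dict)
    species_weights: dict[str, float] = field(default_factory=dict)
    host_peptides: set[str] = field(default_factory=set)
    #: per study: list of (peptide key, source genome or "host")
    sampled: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "ortholog_groups": self.ortholog_groups,
            "protein_ortholog": self.protein_ortholog,
            "missing_proteins": sorted(self.missing_proteins),
            "cog_s_proteins": sorted(self.cog_s_proteins),
            "family_of": self.family_of,
            "species_weights": self.species_weights,
            "host_peptides": sorted(self.host_peptides),
            "sampled": {s: [list(t) for t in v] for s, v in self.sampled.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rng(config: SynthesisConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _residue_probs() -> np.ndarray:
    probs = np.empty(len(RESIDUES))
    other = (1 - 2 / 18) / (len(RESIDUES) - 2)
    for i, r in enumerate(RESIDUES):
        probs[i] = 1 / 18 if r in "KR" else other
    return probs


_PROBS = _residue_probs()


def _random_protein(rng: np.random.Generator, mean_length: int) -> str:
    length = 30 + rng.geometric(1 / (mean_length - 29)) - 1
    return "".join(rng.choice(RESIDUES, size=length, p=_PROBS))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [r for r in RESIDUES if r != chars[i]]
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def generate_catalog(config: SynthesisConfig) -> tuple[ProteinCatalog, GroundTruth]:
    """Generate the ranked taxonomy and per-species proteomes.

    Each genus's first species donates ortholog seeds; every sister
    species replaces its corresponding protein slots with mutated copies.
    """
    rng = _rng(config, _STREAM_CATALOG)
    truth = GroundTruth(config=config)
    n_share = round(config.ortholog_share_rate * config.proteins_per_genome)

    lineages: dict[str, Lineage] = {}
    proteins: list[ProteinRecord] = []
    genome_idx = 0
    genus_idx = 0
    for p in range(config.n_phyla):
        for c in range(config.classes_per_phylum):
            for o in range(config.orders_per_class):
                for f in range(config.families_per_order):
                    for g in range(config.genera_per_family):
                        genus_idx += 1
                        donors: list[str] | None = None
                        for s in range(config.species_per_genus):
                            genome_idx += 1
                            genome = f"GENOME{genome_idx:05d}"
                            lineages[genome] = Lineage(
                                (
                                    "Bacteria",
                                    f"Phylum{p + 1:02d}",
                                    f"Class{p + 1:02d}.{c + 1}",
                                    f"Order{p + 1:02d}.{c + 1}.{o + 1}",
                                    f"Family{p + 1:02d}.{c + 1}.{o + 1}.{f + 1}",
                                    f"Genus{genus_idx:04d}",
                                    f"Species{genome_idx:05d}",
                                )
                            )
                            seqs: list[str] = []
                            if s == 0:
                                for j in range(config.proteins_per_genome):
                                    seqs.append(_random_protein(rng, config.mean_protein_length))
                                donors = seqs[:n_share]
                            else:
                                assert donors is not None
                                for j in range(n_share):
                                    seqs.append(
                                        _mutate(donors[j], config.ortholog_mutation_rate, rng)
                                    )
                                for j in range(n_share, config.proteins_per_genome):
                                    seqs.append(_random_protein(rng, config.mean_protein_length))
                            for j, seq in enumerate(seqs):
                                pid = f"{genome}_{j + 1:05d}"
                                proteins.append(ProteinRecord(pid, genome, seq))
                                if j < n_share:
                                    og = f"OG{genus_idx:04d}_{j + 1:05d}"
                                    truth.ortholog_groups.setdefault(og, []).append(pid)
                                    truth.protein_ortholog[pid] = og

    catalog = ProteinCatalog(proteins)
    catalog.attach_lineages(lineages)
    return catalog, truth


def generate_host_proteome(config: SynthesisConfig) -> list[ProteinRecord]:
    """Random host (human-stand-in) proteins under the same sequence model."""
    rng = _rng(config, _STREAM_HOST)
    return [
        ProteinRecord(f"HUMAN_{i + 1:05d}", "HUMAN", _random_protein(rng, config.mean_protein_length))
        for i in range(config.n_host_proteins)
    ]


def generate_annotations(
    catalog: ProteinCatalog, config: SynthesisConfig, truth: GroundTruth
) -> dict[str, AnnotationRecord]:
    """Annotation table with controlled missingness and category-S rate.

    The annotation unit is the ortholog group (copies inherit the same
    COG family) or the single private protein. With probability
    ``annotation_missing_rate`` a unit is fully unannotated; with
    probability ``cog_s_rate`` it carries the dedicated unknown-function
    family with category S (keeping a KEGG ko, so the no-ko-and-no-GO
    fraction tracks ``annotation_missing_rate`` alone); otherwise it gets
    a unit-unique COG family, categories, ko and GO term.
    """
    rng = _rng(config, _STREAM_ANNOT)
    units: list[list[str]] = [truth.ortholog_groups[og] for og in sorted(truth.ortholog_groups)]
    units += [[p.protein_id] for p in catalog.proteins if p.protein_id not in truth.protein_ortholog]

    records: dict[str, AnnotationRecord] = {}
    fam_counter = 0
    for members in units:
        u = rng.random()
        if u < config.annotation_missing_rate:
            fam: str | None = None
            cats: frozenset[str] = frozenset()
            kos: frozenset[str] = frozenset()
            gos: frozenset[str] = frozenset()
            truth.missing_proteins.update(members)
        elif u < config.annotation_missing_rate + config.cog_s_rate:
            fam = UNKNOWN_FAMILY
            cats = frozenset("S")
            kos = frozenset({"ko:K99999"})
            gos = frozenset()
            truth.cog_s_proteins.update(members)
        else:
            fam_counter += 1
            fam = f"COG{fam_counter:05d}"
            n_cats = 2 if rng.random() < 0.10 else 1
            cats = frozenset(rng.choice(COG_LETTERS, size=n_cats, replace=False))
            kos = frozenset({f"ko:K{fam_counter:05d}"})
            gos = frozenset({f"GO:{fam_counter:07d}"})
        for pid in members:
            if fam is not None:
                truth.family_of[pid] = fam
            records[pid] = AnnotationRecord(pid, fam, cats, kos, gos)
    return records


def simulate_identifications(
    catalog: ProteinCatalog,
    host_proteins: Sequence[ProteinRecord],
    config: SynthesisConfig,
    truth: GroundTruth,
    params: DigestionParams = DigestionParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample identified-peptide and protein-group tables.

    Per-species sampling weights are one Dirichlet draw with
    concentration ``abundance_skew`` shared across studies (smaller skew
    = more uneven community); each draw picks a host peptide with
    probability ``host_fraction``, else a uniform peptide from the drawn
    species' in-silico pool. Intensities are log-normal. Per study, each
    sampled microbial peptide yields a protein group of all catalog
    proteins containing it (sorted; head = first); identical member
    lists within a study are merged with summed intensity.
    """
    rng = _rng(config, _STREAM_IDENT)
    genomes = sorted(catalog.genomes)
    by_genome = catalog.proteins_by_genome()
    pools: dict[str, list[str]] = {
        g: sorted(digest_peptide_pool((p.sequence for p in by_genome[g]), params)) for g in genomes
    }
    host_pool = sorted(digest_peptide_pool((p.sequence for p in host_proteins), params))
    truth.host_peptides = set(host_pool)
    total_pool = len(set().union(*pools.values(), host_pool))
    if config.n_identified_peptides > total_pool:
        raise ValueError(
            f"n_identified_peptides={config.n_identified_peptides} exceeds pool size {total_pool}"
        )

    weights = rng.dirichlet(np.full(len(genomes), config.abundance_skew))
    truth.species_weights = {g: float(w) for g, w in zip(genomes, weights)}

    index = build_index(catalog, params)
    studies = [f"S{i + 1}" for i in range(config.n_studies)]
    per_study = [config.n_identified_peptides // config.n_studies] * config.n_studies
    per_study[0] += config.n_identified_peptides - sum(per_study)

    pep_rows: list[dict] = []
    group_rows: list[dict] = []
    for study, n_draws in zip(studies, per_study):
        agg: dict[str, float] = {}
        log: list[tuple[str, str]] = []
        is_host = rng.random(n_draws) < config.host_fraction
        genome_idx = rng.choice(len(genomes), size=n_draws, p=weights)
        pick = rng.random(n_draws)  # uniform position within the chosen pool
        intensities = rng.lognormal(mean=13.8, sigma=1.5, size=n_draws)
        for i in range(n_draws):
            if is_host[i]:
                pep = host_pool[int(pick[i] * len(host_pool))]
                source = "host"
            else:
                pool = pools[genomes[genome_idx[i]]]
                pep = pool[int(pick[i] * len(pool))]
                source = genomes[genome_idx[i]]
            agg[pep] = agg.get(pep, 0.0) + float(intensities[i])
            log.append((pep, source))
        truth.sampled[study] = log
        for pep in sorted(agg):
            pep_rows.append({"peptide": pep, "study": study, "intensity": agg[pep]})

        merged: dict[tuple[str, ...], float] = {}
        for pep in sorted(agg):
            members = tuple(sorted(index.proteins_of(pep)))
            if not members:
                continue  # host-only or unmapped peptide: no catalog group
            merged[members] = merged.get(members, 0.0) + agg[pep]
        for members in sorted(merged):
            group_rows.append({"study": study, "members": members, "intensity": merged[members]})

    peptides = pd.DataFrame(pep_rows, columns=["peptide", "study", "intensity"])
    groups = pd.DataFrame(group_rows, columns=["study", "members", "intensity"])
    return peptides, groups


def synthesize_to_dir(
    config: SynthesisConfig,
    out_dir: str | Path,
    params: DigestionParams = DigestionParams(),
) -> dict[str, Path]:
    """Generate a complete input set on disk in the formats catalog_io reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog, truth = generate_catalog(config)
    host = generate_host_proteome(config)
    annotations = generate_annotations(catalog, config, truth)
    peptides, groups = simulate_identifications(catalog, host, config, truth, params)

    paths = {
        "catalog_fasta": out_dir / "catalog.faa",
        "host_fasta": out_dir / "host.faa",
        "lineage": out_dir / "lineage.tsv",
        "annotations": out_dir / "annotations.tsv",
        "peptides": out_dir / "identified_peptides.tsv",
        "groups": out_dir / "protein_groups.tsv",
        "ledger": out_dir / "ground_truth.json",
    }
    write_protein_fasta(catalog, paths["catalog_fasta"])
    host_catalog = ProteinCatalog(list(host))
    write_protein_fasta(host_catalog, paths["host_fasta"])
    write_lineage_table(catalog.lineages, paths["lineage"])
    write_annotation_table(annotations, paths["annotations"])
    write_identified_peptides(peptides, paths["peptides"])
    write_protein_groups(groups, paths["groups"])
    truth.to_json(paths["ledger"])
    return paths
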