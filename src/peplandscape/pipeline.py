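"""End-to-end orchestration of the landscape analysis.

Stages run in dependency order: digest → index → host partition → LCA
assignment → coverage → annotation accounting → functional
distinctness → composition → exports. All data go to files under the
output directory; logging goes to stderr. Identical inputs and config
produce byte-identical outputs (the run manifest contains no clocks).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import catalog_io, composition, coverage, function_annotation, taxa_assign
from .catalog_io import RANKS
from .digestion import DigestionParams, digest_peptide_pool

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    catalog_fasta: list[str | Path]
    lineage_table: str | Path
    annotation_table: str | Path
    host_fasta: str | Path
    peptide_table: str | Path
    group_table: str | Path
    out_dir: str | Path
    digestion: DigestionParams = field(default_factory=DigestionParams)
    sparse_threshold: int = 5
    min_proteins: int = 100
    decile: float = 0.10
    top_n: int = 30
    bacteria_only: bool = False
    genome_id_regex: str = catalog_io.DEFAULT_GENOME_ID_REGEX

    def input_paths(self) -> list[Path]:
        return [Path(p) for p in self.catalog_fasta] + [
            Path(self.lineage_table),
            Path(self.annotation_table),
            Path(self.host_fasta),
            Path(self.peptide_table),
            Path(self.group_table),
        ]

    def validate(self) -> None:
        missing = [str(p) for p in self.input_paths() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if not 0 < self.decile <= 1:
            raise ValueError("decile must be in (0,1]")
        if self.sparse_threshold < 0 or self.min_proteins < 1 or self.top_n < 1:
            raise ValueError("thresholds out of range")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][path.name] = len(df)


class _Stage:
    """Context manager that labels failures with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"stage {self.name} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def run_landscape(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.digestion
    # config echo uses basenames and omits out_dir so identical inputs +
    # analysis settings give byte-identical manifests wherever they run
    path_fields = {"lineage_table", "annotation_table", "host_fasta", "peptide_table", "group_table"}
    manifest: dict = {
        "config": {
            **{
                k: (Path(str(v)).name if k in path_fields else v)
                for k, v in dataclasses.asdict(config).items()
                if k not in ("digestion", "out_dir")
            },
            "catalog_fasta": [Path(str(p)).name for p in config.catalog_fasta],
            "digestion": dataclasses.asdict(params),
        },
        "inputs": {p.name: _sha256(p) for p in config.input_paths()},
        "outputs": {},
    }

    with _Stage("read_inputs"):
        catalog = catalog_io.read_protein_fasta(config.catalog_fasta, config.genome_id_regex)
        lineages = catalog_io.read_lineage_table(config.lineage_table)
        catalog.attach_lineages(lineages)
        annotations = catalog_io.read_annotation_table(config.annotation_table, catalog)
        host = catalog_io.read_protein_fasta([config.host_fasta], r"^(?P<genome>.+?)_\d+$")
        peptides = catalog_io.read_identified_peptides(config.peptide_table)
        groups = catalog_io.read_protein_groups(config.group_table)

    with _Stage("digest_index"):
        index = taxa_assign.build_index(catalog, params)
        per_genome = index.per_genome_sets()
        for g in catalog.genomes:
            per_genome.setdefault(g, set())
        counts = pd.DataFrame(
            {
                "genome": sorted(per_genome),
                "n_unique_peptides": [len(per_genome[g]) for g in sorted(per_genome)],
            }
        )
        _write(counts, out / "per_genome_peptide_counts.tsv", manifest)
        host_peptides = digest_peptide_pool((p.sequence for p in host.proteins), params)

    with _Stage("partition_host"):
        unique_peptides = set(peptides["peptide"])
        partition = taxa_assign.partition_host(unique_peptides, host_peptides, index)
        part_df = pd.DataFrame(
            {
                "status": ["host_only", "shared_host_microbial", "microbial", "unmapped"],
                "n_peptides": [
                    len(partition.host_only),
                    len(partition.shared_host_microbial),
                    len(partition.microbial),
                    len(partition.unmapped),
                ],
            }
        )
        _write(part_df, out / "host_partition.tsv", manifest)

    with _Stage("assign"):
        assignments = taxa_assign.assign_all(partition, index, catalog.lineages)
        assign_df = pd.DataFrame(
            {
                "peptide": [a.peptide for a in assignments.values()],
                "status": [a.status.value for a in assignments.values()],
                "rank": [a.rank if a.rank else catalog_io.ABSENT for a in assignments.values()],
                "taxon": [a.taxon if a.taxon else catalog_io.ABSENT for a in assignments.values()],
                "genome_distinct": [int(a.genome_distinct) for a in assignments.values()],
            }
        )
        _write(assign_df, out / "assignments.tsv", manifest)
        distinct_df, rank_tally = taxa_assign.genome_distinct_counts(
            assignments, catalog, config.bacteria_only
        )
        _write(distinct_df, out / "genome_distinct_counts.tsv", manifest)
        _write(rank_tally, out / "rank_tally.tsv", manifest)

    with _Stage("coverage"):
        pep_cov = coverage.peptide_coverage(partition.retained, index, per_genome, catalog)
        _write(pep_cov, out / "peptide_coverage.tsv", manifest)
        head_set, head_prov = coverage.head_protein_extraction(groups)
        _write(head_prov, out / "head_proteins.tsv", manifest)
        prot_cov, bin_summary = coverage.protein_coverage(head_set, catalog)
        _write(prot_cov, out / "protein_coverage.tsv", manifest)
        _write(bin_summary, out / "coverage_bins.tsv", manifest)
        sparse = coverage.sparse_species_report(distinct_df, config.sparse_threshold)
        sparse_df = pd.DataFrame(
            {"metric": ["n_sparse_species", "n_zero_species"], "value": [sparse.n_sparse, sparse.n_zero]}
        )
        _write(sparse_df, out / "sparse_species.tsv", manifest)
        _write(sparse.family_contributors, out / "sparse_families.tsv", manifest)
        _write(sparse.genus_contributors, out / "sparse_genera.tsv", manifest)

    with _Stage("annotation"):
        summary = function_annotation.annotation_summary(head_set, annotations)
        summary_df = pd.DataFrame(
            {
                "metric": ["n_head_proteins", "n_no_ko_go", "pct_no_ko_go", "n_cog_unknown", "pct_cog_unknown"],
                "value": [
                    summary.n_total,
                    summary.n_no_ko_go,
                    summary.pct_no_ko_go,
                    summary.n_cog_unknown,
                    summary.pct_cog_unknown,
                ],
            }
        )
        _write(summary_df, out / "annotation_summary.tsv", manifest)
        n_high, high_df = function_annotation.high_abundance_unannotated(
            groups, annotations, config.decile
        )
        _write(high_df, out / "high_abundance_unannotated.tsv", manifest)
        ratio_df = function_annotation.species_annotation_ratio(
            head_set, annotations, catalog, config.min_proteins
        )
        _write(ratio_df, out / "species_annotation_ratio.tsv", manifest)

    with _Stage("distinctness"):
        classes = function_annotation.functional_distinctness(index, annotations)
        frac = classes.fractions
        classes_df = pd.DataFrame(
            {
                "class": ["functional_distinct", "unannotated_distinct", "shared_multi_family"],
                "n_peptides": [
                    classes.n_functional_distinct,
                    classes.n_unannotated_distinct,
                    classes.n_shared_multi_family,
                ],
                "pct": [
                    frac["functional_distinct"],
                    frac["unannotated_distinct"],
                    frac["shared_multi_family"],
                ],
            }
        )
        _write(classes_df, out / "functional_classes.tsv", manifest)

    with _Stage("composition"):
        ref_frames, pep_frames = [], []
        for rank in RANKS:
            ref_frames.append(composition.reference_composition(catalog, rank))
            pep_frames.append(composition.peptide_composition(assignments, rank))
        ref_all = pd.concat(ref_frames, ignore_index=True)
        pep_all = pd.concat(pep_frames, ignore_index=True)
        _write(ref_all, out / "composition_catalog.tsv", manifest)
        _write(pep_all, out / "composition_peptides.tsv", manifest)
        overlap_rows = []
        for rank in ("family", "genus"):
            ref_c = ref_all[ref_all["rank"] == rank]
            pep_c = pep_all[pep_all["rank"] == rank]
            n_taxa = max(len(ref_c), len(pep_c))
            n = min(config.top_n, n_taxa) if n_taxa else config.top_n
            count, top_ref, top_pep = composition.top_overlap(ref_c, pep_c, n)
            overlap_rows.append(
                {
                    "rank": rank,
                    "top_n": n,
                    "overlap": count,
                    "top_catalog": ",".join(top_ref),
                    "top_peptides": ",".join(top_pep),
                }
            )
        _write(pd.DataFrame(overlap_rows), out / "top_overlap.tsv", manifest)

    with _Stage("exports"):
        genus_counts: dict[str, int] = {}
        family_counts: dict[str, int] = {}
        for a in assignments.values():
            if a.rank == "genus":
                genus_counts[a.taxon] = genus_counts.get(a.taxon, 0) + 1
            elif a.rank == "family":
                family_counts[a.taxon] = family_counts.get(a.taxon, 0) + 1
        leaves = sorted(distinct_df["species"])
        per_leaf = distinct_df.set_index("species")
        itol_df = pd.DataFrame(
            {
                "genome_distinct": per_leaf["genome_distinct"],
                "genus_lca": [genus_counts.get(g, 0) for g in per_leaf["genus"]],
                "family_lca": [family_counts.get(f, 0) for f in per_leaf["family"]],
                "phylum": per_leaf["phylum"],
            }
        )
        itol = catalog_io.write_itol_datasets(itol_df, leaves, out)
        manifest["outputs"]["itol_peptide_counts.txt"] = len(itol_df)
        manifest["outputs"]["itol_phylum_strip.txt"] = len(itol_df)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("wrote %s", manifest_path)
    return manifest
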