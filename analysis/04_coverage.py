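"""Peptide- and protein-level proteome coverage per species.

Quantifies how much of each species' theoretical peptide universe and
CDS complement is observed among the identifications, bins the protein
coverage, and summarises species with few genome-distinct peptides.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import PARAMS, TABLES, ensure_tables, load_inputs

import pandas as pd

from peplandscape.coverage import (
    head_protein_extraction,
    peptide_coverage,
    protein_coverage,
    sparse_species_report,
)
from peplandscape.taxa_assign import build_index, partition_host


def main() -> None:
    catalog, _, host_peptides, peptides, groups = load_inputs()
    index = build_index(catalog, PARAMS)
    per_genome = index.per_genome_sets()
    for g in catalog.genomes:
        per_genome.setdefault(g, set())
    part = partition_host(set(peptides["peptide"]), host_peptides, index)

    tables = ensure_tables()
    pep_cov = peptide_coverage(part.retained, index, per_genome, catalog)
    pep_cov.to_csv(tables / "peptide_coverage.tsv", sep="\t", index=False)
    best = pep_cov.loc[pep_cov["peptide_coverage_pct"].idxmax()]
    print(f"peptide-level coverage: best-covered species {best['species']} at "
          f"{best['peptide_coverage_pct']}% "
          f"({best['occurring_identified_peptides']}/{best['total_insilico_peptides']} peptides)")

    heads, prov = head_protein_extraction(groups)
    prot_cov, bins = protein_coverage(heads, catalog)
    prot_cov.to_csv(tables / "protein_coverage.tsv", sep="\t", index=False)
    bins.to_csv(tables / "coverage_bins.tsv", sep="\t", index=False)
    bestp = prot_cov.loc[prot_cov["protein_coverage_pct"].idxmax()]
    print(f"protein-level coverage: {len(heads)} unique head proteins; "
          f"best-covered species {bestp['species']} at {bestp['protein_coverage_pct']}% "
          f"({bestp['identified_head_proteins']}/{bestp['cds_count']} CDS)")
    print("coverage bins:", dict(zip(bins["coverage_bin"], bins["n_species"])))

    distinct = pd.read_csv(TABLES / "genome_distinct_counts.tsv", sep="\t")
    sparse = sparse_species_report(distinct, threshold=5)
    print(f"{sparse.n_sparse} species have <=5 genome-distinct peptides "
          f"({sparse.n_zero} with none)")
    sparse.family_contributors.to_csv(tables / "sparse_families.tsv", sep="\t", index=False)
    sparse.genus_contributors.to_csv(tables / "sparse_genera.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
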