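"""Host filtering and taxonomic assignment of identified peptides.

Partitions identified peptides into host-only / shared / microbial,
assigns each retained peptide its genome-distinct species or LCA rank,
and exports the per-species counts plus iTOL annotation files for a
species tree.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import PARAMS, ensure_tables, load_inputs

from peplandscape import catalog_io
from peplandscape.taxa_assign import (
    assign_all,
    build_index,
    genome_distinct_counts,
    partition_host,
)


def main() -> None:
    catalog, _, host_peptides, peptides, _ = load_inputs()
    index = build_index(catalog, PARAMS)
    unique = set(peptides["peptide"])
    part = partition_host(unique, host_peptides, index)
    print(f"{len(unique)} unique identified peptides: "
          f"{len(part.host_only)} host-only (excluded), "
          f"{len(part.shared_host_microbial)} shared host/microbial, "
          f"{len(part.microbial)} microbial, {len(part.unmapped)} unmapped")

    assignments = assign_all(part, index, catalog.lineages)
    distinct, tally = genome_distinct_counts(assignments, catalog)
    n_distinct = int(distinct["genome_distinct"].sum())
    print(f"{n_distinct} peptides are genome-distinct "
          f"({n_distinct / len(assignments):.1%} of retained); "
          f"per-species range {distinct['genome_distinct'].min()}-"
          f"{distinct['genome_distinct'].max()}")

    tables = ensure_tables()
    rows = [
        {"peptide": a.peptide, "status": a.status.value, "rank": a.rank or "-",
         "taxon": a.taxon or "-", "genome_distinct": int(a.genome_distinct)}
        for a in assignments.values()
    ]
    pd.DataFrame(rows).to_csv(tables / "assignments.tsv", sep="\t", index=False)
    distinct.to_csv(tables / "genome_distinct_counts.tsv", sep="\t", index=False)
    tally.to_csv(tables / "rank_tally.tsv", sep="\t", index=False)

    genus_counts: dict[str, int] = {}
    family_counts: dict[str, int] = {}
    for a in assignments.values():
        if a.rank == "genus":
            genus_counts[a.taxon] = genus_counts.get(a.taxon, 0) + 1
        elif a.rank == "family":
            family_counts[a.taxon] = family_counts.get(a.taxon, 0) + 1
    per_leaf = distinct.set_index("species")
    itol_df = pd.DataFrame(
        {
            "genome_distinct": per_leaf["genome_distinct"],
            "genus_lca": [genus_counts.get(g, 0) for g in per_leaf["genus"]],
            "family_lca": [family_counts.get(f, 0) for f in per_leaf["family"]],
            "phylum": per_leaf["phylum"],
        }
    )
    itol = catalog_io.write_itol_datasets(itol_df, sorted(per_leaf.index), tables)
    print(f"wrote assignment tables and iTOL datasets under {tables}")


if __name__ == "__main__":
    main()
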