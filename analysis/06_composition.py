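"""Taxonomic composition: catalog genomes vs identified peptides.

Contrasts the per-rank composition of the reference catalog with the
composition of peptide assignments, and counts the overlap between the
most genome-rich and most peptide-rich taxa.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import PARAMS, ensure_tables, load_inputs

import pandas as pd

from peplandscape.catalog_io import RANKS
from peplandscape.composition import peptide_composition, reference_composition, top_overlap
from peplandscape.taxa_assign import assign_all, build_index, partition_host


def main() -> None:
    catalog, _, host_peptides, peptides, _ = load_inputs()
    index = build_index(catalog, PARAMS)
    part = partition_host(set(peptides["peptide"]), host_peptides, index)
    assignments = assign_all(part, index, catalog.lineages)

    tables = ensure_tables()
    ref_frames, pep_frames = [], []
    for rank in RANKS:
        ref_frames.append(reference_composition(catalog, rank))
        pep_frames.append(peptide_composition(assignments, rank))
    ref_all = pd.concat(ref_frames, ignore_index=True)
    pep_all = pd.concat(pep_frames, ignore_index=True)
    ref_all.to_csv(tables / "composition_catalog.tsv", sep="\t", index=False)
    pep_all.to_csv(tables / "composition_peptides.tsv", sep="\t", index=False)

    phylum_ref = ref_frames[RANKS.index("phylum")].set_index("taxon")["fraction"]
    phylum_pep = pep_frames[RANKS.index("phylum")].set_index("taxon")["fraction"]
    print("phylum-level fractions (catalog vs peptides):")
    for taxon in phylum_ref.index:
        print(f"  {taxon}: {phylum_ref[taxon]:.1%} vs {phylum_pep.get(taxon, 0):.1%}")

    rows = []
    for rank in ("family", "genus"):
        ref_c = ref_all[ref_all["rank"] == rank]
        pep_c = pep_all[pep_all["rank"] == rank]
        n = min(10, max(len(ref_c), len(pep_c)))
        overlap, _, _ = top_overlap(ref_c, pep_c, n)
        rows.append({"rank": rank, "top_n": n, "overlap": overlap})
        print(f"top-{n} {rank} overlap between catalog and peptide views: {overlap}")
    pd.DataFrame(rows).to_csv(tables / "top_overlap.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
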