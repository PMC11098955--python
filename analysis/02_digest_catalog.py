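"""In-silico digestion of the catalog.

Digests every proteome with the identification-matching parameters
(minimum length 7, up to 2 missed cleavages, Trypsin/P) and reports the
per-species unique tryptic peptide universe.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import PARAMS, ensure_tables, load_inputs

from peplandscape.digestion import digest_catalog


def main() -> None:
    catalog, *_ = load_inputs()
    per_genome, counts = digest_catalog(catalog, PARAMS)
    out = ensure_tables() / "per_genome_peptide_counts.tsv"
    counts.to_csv(out, sep="\t", index=False)
    total = counts["n_unique_peptides"].sum()
    print(f"digested {len(catalog.proteins)} proteins from {len(catalog.genomes)} genomes")
    print(f"species peptide universes: {counts['n_unique_peptides'].min()}-"
          f"{counts['n_unique_peptides'].max()} unique peptides "
          f"(sum over species {total})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
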