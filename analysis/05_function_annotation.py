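"""Annotation coverage of identified proteins and peptide-space
functional distinctness.

Reports the broad (no KEGG ko and no GO) and strict (no COG family or
category S only) unannotated fractions of the identified head proteins,
the highly abundant unannotated proteins (top intensity decile in any
study), per-species annotation ratios, and the COG-family distinctness
classes of the catalog's unique peptide space.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import PARAMS, ensure_tables, load_inputs

import pandas as pd

from peplandscape.coverage import head_protein_extraction
from peplandscape.function_annotation import (
    annotation_summary,
    functional_distinctness,
    high_abundance_unannotated,
    species_annotation_ratio,
)
from peplandscape.taxa_assign import build_index


def main() -> None:
    catalog, annotations, _, _, groups = load_inputs()
    heads, _ = head_protein_extraction(groups)
    tables = ensure_tables()

    summary = annotation_summary(heads, annotations)
    print(f"{summary.n_total} unique head proteins: "
          f"{summary.n_no_ko_go} ({summary.pct_no_ko_go}%) lack both ko and GO; "
          f"{summary.n_cog_unknown} ({summary.pct_cog_unknown}%) are COG-unknown")

    n_high, high_df = high_abundance_unannotated(groups, annotations, decile=0.10)
    high_df.to_csv(tables / "high_abundance_unannotated.tsv", sep="\t", index=False)
    print(f"{n_high} COG-unknown head proteins sit in the top intensity decile of some study")

    ratios = species_annotation_ratio(heads, annotations, catalog, min_proteins=100)
    ratios.to_csv(tables / "species_annotation_ratio.tsv", sep="\t", index=False)
    if len(ratios):
        print(f"per-species annotated fraction (>=100 identified proteins): "
              f"{ratios['annotated_pct'].min()}-{ratios['annotated_pct'].max()}% "
              f"across {len(ratios)} species")
    else:
        print("no species reaches 100 identified proteins at this scale")

    index = build_index(catalog, PARAMS)
    classes = functional_distinctness(index, annotations)
    frac = classes.fractions
    pd.DataFrame(
        {
            "class": list(frac),
            "n_peptides": [classes.n_functional_distinct, classes.n_unannotated_distinct,
                           classes.n_shared_multi_family],
            "pct": list(frac.values()),
        }
    ).to_csv(tables / "functional_classes.tsv", sep="\t", index=False)
    print(f"of {classes.n_total_unique} unique catalog peptides: "
          f"{frac['functional_distinct']}% functional-distinct, "
          f"{frac['unannotated_distinct']}% exclusive to unannotated proteins, "
          f"{frac['shared_multi_family']}% shared across COG families")


if __name__ == "__main__":
    main()
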