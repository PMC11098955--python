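"""Shared plumbing for the numbered analysis drivers: default locations
and input loading. All computation lives in the peplandscape package."""

from __future__ import annotations

from pathlib import Path

from peplandscape import catalog_io
from peplandscape.digestion import DigestionParams, digest_peptide_pool

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"

PARAMS = DigestionParams()  # min length 7, <=2 missed cleavages, Trypsin/P


def load_inputs():
    catalog = catalog_io.read_protein_fasta([DATA / "catalog.faa"])
    catalog.attach_lineages(catalog_io.read_lineage_table(DATA / "lineage.tsv"))
    annotations = catalog_io.read_annotation_table(DATA / "annotations.tsv", catalog)
    host = catalog_io.read_protein_fasta([DATA / "host.faa"], r"^(?P<genome>.+?)_\d+$")
    host_peptides = digest_peptide_pool((p.sequence for p in host.proteins), PARAMS)
    peptides = catalog_io.read_identified_peptides(DATA / "identified_peptides.tsv")
    groups = catalog_io.read_protein_groups(DATA / "protein_groups.tsv")
    return catalog, annotations, host_peptides, peptides, groups


def ensure_tables() -> Path:
    TABLES.mkdir(parents=True, exist_ok=True)
    return TABLES
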