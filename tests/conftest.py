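"""Shared fixtures: a hand-built micro-catalog with planted peptides for
exact LCA/host checks, and a seeded synthetic bundle for ledger-based
checks."""

from __future__ import annotations

import pytest

from peplandscape.catalog_io import Lineage, ProteinCatalog, ProteinRecord
from peplandscape.digestion import DigestionParams
from peplandscape.synthetic_data import (
    SynthesisConfig,
    generate_annotations,
    generate_catalog,
    generate_host_proteome,
    simulate_identifications,
)

# Planted tryptic peptides (each ends in K, length 8, no internal sites)
PEP_SP1_ONLY = "DDDDDDDK"      # only in G1 -> genome-distinct, species Sp1
PEP_GENUS = "EEEEEEEK"         # in G1 and G2 (same genus) -> genus LCA
PEP_CROSS_PHYLUM = "FFFFFFFK"  # in G1 and G3 (different phyla) -> domain LCA
PEP_CROSS_DOMAIN = "GGGGGGGK"  # in G1 and G4 (Archaea) -> no shared rank
PEP_HOST_SHARED = "HHHHHHHK"   # in G1 and the host -> shared_host_microbial


def _lineage(phylum: str, genus: str, species: str, domain: str = "Bacteria") -> Lineage:
    return Lineage((domain, phylum, f"C_{phylum}", f"O_{phylum}", f"F_{phylum}", genus, species))


@pytest.fixture
def tiny_catalog() -> ProteinCatalog:
    proteins = [
        ProteinRecord("G1_00001", "G1", PEP_SP1_ONLY + PEP_GENUS),
        ProteinRecord("G1_00002", "G1", PEP_CROSS_PHYLUM + PEP_CROSS_DOMAIN + PEP_HOST_SHARED),
        ProteinRecord("G2_00001", "G2", PEP_GENUS),
        ProteinRecord("G3_00001", "G3", PEP_CROSS_PHYLUM),
        ProteinRecord("G4_00001", "G4", PEP_CROSS_DOMAIN),
    ]
    catalog = ProteinCatalog(proteins)
    catalog.attach_lineages(
        {
            "G1": _lineage("P1", "Gen1", "Sp1"),
            "G2": _lineage("P1", "Gen1", "Sp2"),
            "G3": _lineage("P2", "Gen2", "Sp3"),
            "G4": _lineage("P3", "Gen3", "Sp4", domain="Archaea"),
        }
    )
    return catalog


@pytest.fixture
def default_params() -> DigestionParams:
    return DigestionParams()


@pytest.fixture(scope="session")
def synth_bundle():
    """Default-condition synthetic dataset with its ground-truth ledger."""
    config = SynthesisConfig(seed=1)
    catalog, truth = generate_catalog(config)
    host = generate_host_proteome(config)
    annotations = generate_annotations(catalog, config, truth)
    peptides, groups = simulate_identifications(catalog, host, config, truth)
    return {
        "config": config,
        "catalog": catalog,
        "truth": truth,
        "host": host,
        "annotations": annotations,
        "peptides": peptides,
        "groups": groups,
    }
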