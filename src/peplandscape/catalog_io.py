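"""Domain types and I/O for the reference catalog and result tables.

The pipeline's universe is a multi-genome protein catalog (one proteome
per representative genome, GTDB-style 7-rank lineages), an eggNOG-style
functional annotation table, a host proteome, and the peptide / protein
group identification tables compiled from metaproteomics studies. All
tabular formats are tab-separated UTF-8 with a header line; absence is
always an explicit ``-`` marker, never an empty string. Every writer has
a matching reader and round-trips exactly.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_DEPTH: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")
VALID_RESIDUES = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES

ABSENT = "-"

#: default rule: genome ID is everything before the trailing _<protein index>
DEFAULT_GENOME_ID_REGEX = r"^(?P<genome>.+)_\d+$"


@dataclass(frozen=True, order=True)
class Lineage:
    """A ranked lineage over the fixed 7-rank ladder domain→species."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"rank ladder incomplete: expected {len(RANKS)} ranks, got {len(self.names)}")
        if any(not n for n in self.names):
            raise ValueError("lineage contains an empty taxon name")

    @classmethod
    def from_string(cls, s: str) -> "Lineage":
        parts = s.strip().split(";")
        if len(parts) != len(RANKS):
            raise ValueError(f"rank ladder incomplete: {len(parts)} ranks in {s!r}")
        names = []
        for part, prefix in zip(parts, RANK_PREFIXES):
            part = part.strip()
            if not part.startswith(prefix):
                raise ValueError(f"unknown rank prefix in {part!r} (expected {prefix!r})")
            name = part[len(prefix):]
            if not name:
                raise ValueError(f"empty taxon name at prefix {prefix!r} in {s!r}")
            names.append(name)
        return cls(tuple(names))

    def to_string(self) -> str:
        return ";".join(p + n for p, n in zip(RANK_PREFIXES, self.names))

    def name_at(self, rank: str) -> str:
        return self.names[RANK_DEPTH[rank]]

    @property
    def species(self) -> str:
        return self.names[-1]


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    sequence: str

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_RESIDUES for c in self.sequence)


@dataclass
class ProteinCatalog:
    """The matching universe: genomes, their proteins, and lineages."""

    proteins: list[ProteinRecord]
    lineages: dict[str, Lineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.proteins:
            if p.protein_id in seen:
                raise ValueError(f"duplicate protein ID {p.protein_id!r}")
            seen.add(p.protein_id)
            if not p.sequence:
                raise ValueError(f"empty sequence for protein {p.protein_id!r}")
            bad = set(p.sequence) - VALID_RESIDUES
            if bad:
                raise ValueError(f"invalid residues {sorted(bad)} in protein {p.protein_id!r}")

    @property
    def genomes(self) -> set[str]:
        return {p.genome_id for p in self.proteins}

    def attach_lineages(self, lineages: Mapping[str, Lineage]) -> None:
        missing = self.genomes - set(lineages)
        if missing:
            raise ValueError(f"genomes without lineage entry: {sorted(missing)[:5]}")
        species = [lineages[g].species for g in sorted(self.genomes)]
        if len(species) != len(set(species)):
            raise ValueError("species names not unique across catalog genomes")
        self.lineages = dict(lineages)

    def proteins_by_genome(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {}
        for p in self.proteins:
            out.setdefault(p.genome_id, []).append(p)
        return out

    def cds_counts(self) -> dict[str, int]:
        """CDS per species proteome = proteins in the representative genome."""
        out: dict[str, int] = {}
        for p in self.proteins:
            out[p.genome_id] = out.get(p.genome_id, 0) + 1
        return out

    def species_of(self, genome_id: str) -> str:
        return self.lineages[genome_id].species

    def protein_index(self) -> dict[str, ProteinRecord]:
        return {p.protein_id: p for p in self.proteins}


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-protein functional annotation as the table states it (no inference)."""

    protein_id: str
    cog_family: str | None = None
    cog_categories: frozenset[str] = frozenset()
    kegg_ko: frozenset[str] = frozenset()
    go_terms: frozenset[str] = frozenset()


def read_protein_fasta(
    paths: Sequence[str | Path],
    genome_id_regex: str = DEFAULT_GENOME_ID_REGEX,
) -> ProteinCatalog:
    """Read one-or-more protein FASTA files into a catalog.

    The genome ID is extracted from each record ID (text before the first
    whitespace) with ``genome_id_regex``, which must expose a ``genome``
    group. Sequences are upper-cased; duplicate protein IDs are rejected.
    """
    pattern = re.compile(genome_id_regex)
    proteins: list[ProteinRecord] = []
    for path in paths:
        n_before = len(proteins)
        for rec in SeqIO.parse(str(path), "fasta"):
            m = pattern.match(rec.id)
            if not m:
                raise ValueError(f"unparsable header {rec.id!r} in {path}: no genome-ID match")
            proteins.append(ProteinRecord(rec.id, m.group("genome"), str(rec.seq).upper()))
        if len(proteins) == n_before:
            warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    catalog = ProteinCatalog(proteins)
    flagged = [p.protein_id for p in proteins if p.has_ambiguous]
    if flagged:
        logger.info("%d proteins carry ambiguity residues (kept, flagged)", len(flagged))
    return catalog


def write_protein_fasta(catalog: ProteinCatalog, path: str | Path, wrap: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in catalog.proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), wrap):
                fh.write(p.sequence[i : i + wrap] + "\n")


def read_lineage_table(path: str | Path) -> dict[str, Lineage]:
    """Read a two-column TSV (genome, 7-rank prefixed lineage string)."""
    out: dict[str, Lineage] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return out
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            genome, lineage_str = fields
            if genome in out:
                raise ValueError(f"{path}:{lineno}: duplicate genome row {genome!r}")
            out[genome] = Lineage.from_string(lineage_str)
    return out


def write_lineage_table(lineages: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome\tlineage\n")
        for genome in sorted(lineages):
            fh.write(f"{genome}\t{lineages[genome].to_string()}\n")


def _split_set(cell: str) -> frozenset[str]:
    if cell == ABSENT or cell == "":
        return frozenset()
    return frozenset(x for x in cell.split(",") if x)


def read_annotation_table(
    path: str | Path, catalog: ProteinCatalog | None = None
) -> dict[str, AnnotationRecord]:
    """Read the per-protein annotation TSV.

    Columns: protein, cog_family, cog_categories (letters, unseparated),
    kegg_ko (comma-joined), go_terms (comma-joined). ``-`` marks absence.
    Protein IDs absent from the catalog are kept with a warning so the
    annotation file may be a superset of the catalog.
    """
    known = {p.protein_id for p in catalog.proteins} if catalog is not None else None
    out: dict[str, AnnotationRecord] = {}
    extra = 0
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            pid, fam, cats, kos, gos = fields
            if known is not None and pid not in known:
                extra += 1
            out[pid] = AnnotationRecord(
                protein_id=pid,
                cog_family=None if fam in (ABSENT, "") else fam,
                cog_categories=frozenset(cats) if cats not in (ABSENT, "") else frozenset(),
                kegg_ko=_split_set(kos),
                go_terms=_split_set(gos),
            )
    if extra:
        warnings.warn(f"{extra} annotation rows not in catalog (kept)", stacklevel=2)
    return out


def write_annotation_table(records: Mapping[str, AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tcog_family\tcog_categories\tkegg_ko\tgo_terms\n")
        for pid in sorted(records):
            r = records[pid]
            fam = r.cog_family if r.cog_family is not None else ABSENT
            cats = "".join(sorted(r.cog_categories)) or ABSENT
            kos = ",".join(sorted(r.kegg_ko)) or ABSENT
            gos = ",".join(sorted(r.go_terms)) or ABSENT
            fh.write(f"{pid}\t{fam}\t{cats}\t{kos}\t{gos}\n")


def read_identified_peptides(path: str | Path) -> pd.DataFrame:
    """Identified-peptide TSV → DataFrame (peptide, study, intensity).

    Duplicate (peptide, study) pairs are collapsed with summed intensity;
    intensity ``-`` becomes NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "study": str}, na_values=[ABSENT])
    expected = ["peptide", "study", "intensity"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    bad = df["peptide"].map(lambda s: bool(set(s) - VALID_RESIDUES))
    if bad.any():
        raise ValueError(f"{path}: invalid peptide sequences, e.g. {df.loc[bad, 'peptide'].iloc[0]!r}")
    if df.duplicated(["peptide", "study"]).any():
        df = df.groupby(["peptide", "study"], as_index=False, sort=False)["intensity"].sum(min_count=1)
    return df


def write_identified_peptides(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["intensity"] = out["intensity"].map(lambda v: ABSENT if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def read_protein_groups(path: str | Path) -> pd.DataFrame:
    """Protein-group TSV → DataFrame (study, members: tuple, intensity)."""
    df = pd.read_csv(path, sep="\t", dtype={"study": str, "members": str}, na_values=[ABSENT])
    expected = ["study", "members", "intensity"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    df["members"] = df["members"].map(lambda s: tuple(s.split(";")))
    if (df["members"].map(len) == 0).any():
        raise ValueError(f"{path}: empty protein-group member list")
    return df


def write_protein_groups(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["members"] = out["members"].map(";".join)
    out["intensity"] = out["intensity"].map(lambda v: ABSENT if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


# -- iTOL dataset export -----------------------------------------------------

#: stable qualitative palette for phylum strips (matplotlib tab10 hexes)
_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def phylum_colors(phyla: Iterable[str]) -> dict[str, str]:
    """Deterministic phylum→hex assignment (sorted order, palette cycles)."""
    return {p: _PALETTE[i % len(_PALETTE)] for i, p in enumerate(sorted(set(phyla)))}


def write_itol_datasets(
    per_leaf: pd.DataFrame,
    tree_leaves: Sequence[str],
    out_dir: str | Path,
) -> dict[str, object]:
    """Emit iTOL annotation files for a species tree.

    ``per_leaf`` is indexed by species (leaf label) with integer columns
    ``genome_distinct``, ``genus_lca``, ``family_lca`` and a string column
    ``phylum``. Two files are written: a MULTIBAR dataset with the three
    peptide counts and a COLORSTRIP dataset coloring leaves by phylum.
    Species absent from the tree are returned in ``skipped`` (and logged),
    never silently dropped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    leafset = list(tree_leaves)
    skipped = sorted(set(per_leaf.index) - set(leafset))
    if skipped:
        logger.warning("%d species absent from tree, skipped: %s ...", len(skipped), skipped[:3])
    present = [l for l in leafset if l in per_leaf.index]
    if not present:
        warnings.warn("empty report: header-only iTOL files written", stacklevel=2)

    bar_path = out_dir / "itol_peptide_counts.txt"
    with open(bar_path, "w", encoding="utf-8") as fh:
        fh.write("DATASET_MULTIBAR\n")
        fh.write("SEPARATOR COMMA\n")
        fh.write("DATASET_LABEL,identified peptide counts\n")
        fh.write("COLOR,#1f77b4\n")
        fh.write("FIELD_COLORS,#1f77b4,#ff7f0e,#2ca02c\n")
        fh.write("FIELD_LABELS,genome_distinct,genus_lca,family_lca\n")
        fh.write("DATA\n")
        for leaf in present:
            row = per_leaf.loc[leaf]
            fh.write(f"{leaf},{int(row['genome_distinct'])},{int(row['genus_lca'])},{int(row['family_lca'])}\n")

    colors = phylum_colors(per_leaf["phylum"]) if len(per_leaf) else {}
    strip_path = out_dir / "itol_phylum_strip.txt"
    with open(strip_path, "w", encoding="utf-8") as fh:
        fh.write("DATASET_COLORSTRIP\n")
        fh.write("SEPARATOR COMMA\n")
        fh.write("DATASET_LABEL,phylum\n")
        fh.write("COLOR,#7f7f7f\n")
        fh.write("DATA\n")
        for leaf in present:
            phylum = per_leaf.loc[leaf, "phylum"]
            fh.write(f"{leaf},{colors[phylum]},{phylum}\n")

    return {"multibar": bar_path, "colorstrip": strip_path, "skipped": skipped}
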