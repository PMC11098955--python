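"""In-silico tryptic digestion of protein sequences and whole catalogs.

Trypsin cleaves C-terminally of K and R. The default parameters mirror
the identification pipeline upstream of the compiled peptide tables:
minimum peptide length 7, up to 2 missed cleavages, and Trypsin/P-style
cleavage (no proline suppression) — the proline rule is exposed as a
flag since search engines differ. Peptides overlapping ambiguity
residues (B, J, O, U, X, Z) are dropped by default because exact string
matching is undefined for them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .catalog_io import AMBIGUOUS_RESIDUES, ProteinCatalog


@dataclass(frozen=True)
class DigestionParams:
    min_length: int = 7
    max_missed_cleavages: int = 2
    cleave_before_proline: bool = True  # True = Trypsin/P
    max_length: int | None = None
    equate_IL: bool = False
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")

    def key(self, sequence: str) -> str:
        """Matching key for a peptide: I/L collapsed to L when equated."""
        return sequence.replace("I", "L") if self.equate_IL else sequence

    def _length_ok(self, n: int) -> bool:
        if n < self.min_length:
            return False
        return self.max_length is None or n <= self.max_length


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment with 1-based inclusive residue coordinates."""

    sequence: str
    protein_id: str | None
    start: int
    end: int
    missed_cleavages: int


def cleavage_sites(seq: str, params: DigestionParams) -> list[int]:
    """0-based positions i such that cleavage occurs between seq[i-1] and seq[i]."""
    sites = []
    for i in range(1, len(seq)):
        if seq[i - 1] in "KR" and (params.cleave_before_proline or seq[i] != "P"):
            sites.append(i)
    return sites


def digest_sequence(
    seq: str, params: DigestionParams = DigestionParams(), protein_id: str | None = None
) -> list[Peptide]:
    """Fully-specific tryptic peptides of ``seq``, ordered by (start, end).

    Peptides span between cleavage points (or termini), skipping at most
    ``max_missed_cleavages`` internal sites, with length filters applied.
    """
    if not seq:
        raise ValueError("empty sequence")
    if seq != seq.upper():
        raise ValueError("sequence must be upper-case")
    cuts = [0] + cleavage_sites(seq, params) + [len(seq)]
    # strip a duplicate terminal cut when the protein ends in K/R
    if len(cuts) >= 2 and cuts[-2] == cuts[-1]:
        cuts.pop()
    ambiguous = (
        [i for i, c in enumerate(seq) if c in AMBIGUOUS_RESIDUES] if params.drop_ambiguous else []
    )
    peptides: list[Peptide] = []
    nfrag = len(cuts) - 1
    for i in range(nfrag):
        for k in range(min(params.max_missed_cleavages, nfrag - 1 - i) + 1):
            lo, hi = cuts[i], cuts[i + k + 1]
            if not params._length_ok(hi - lo):
                continue
            if ambiguous and any(lo <= a < hi for a in ambiguous):
                continue
            peptides.append(Peptide(seq[lo:hi], protein_id, lo + 1, hi, k))
    return peptides


def digest_protein_keys(seq: str, params: DigestionParams) -> Iterator[str]:
    """Matching keys of all tryptic peptides of one protein (with repeats)."""
    for pep in digest_sequence(seq, params):
        yield params.key(pep.sequence)


def digest_catalog(
    catalog: ProteinCatalog, params: DigestionParams = DigestionParams()
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-genome distinct peptide sets and a per-genome count table.

    A species' peptide universe is the set of unique peptide sequences
    from all proteins of its representative genome (within-genome
    deduplication).
    """
    per_genome: dict[str, set[str]] = {g: set() for g in catalog.genomes}
    for p in catalog.proteins:
        per_genome[p.genome_id].update(digest_protein_keys(p.sequence, params))
    counts = pd.DataFrame(
        {"genome": sorted(per_genome), "n_unique_peptides": [len(per_genome[g]) for g in sorted(per_genome)]}
    )
    return per_genome, counts


def digest_peptide_pool(sequences: Iterable[str], params: DigestionParams) -> set[str]:
    """Distinct peptide keys across an arbitrary collection of sequences."""
    pool: set[str] = set()
    for seq in sequences:
        pool.update(digest_protein_keys(seq, params))
    return pool


def digestion_oracle(seq: str, params: DigestionParams = DigestionParams()) -> Counter:
    """Brute-force O(n^3) digestion reference: every substring of ``seq``
    whose boundaries are valid cleavage points or termini and whose count
    of internal cleavage points is within the missed-cleavage budget.

    Independent of :func:`digest_sequence`; returns a sequence multiset.
    Intended for tests and validation only.
    """
    n = len(seq)

    def is_cut(i: int) -> bool:  # boundary between seq[i-1] and seq[i]
        if i <= 0 or i >= n:
            return False
        if seq[i - 1] not in "KR":
            return False
        if not params.cleave_before_proline and seq[i] == "P":
            return False
        return True

    out: Counter = Counter()
    for a in range(n):
        for b in range(a + 1, n + 1):
            if not (a == 0 or is_cut(a)):
                continue
            if not (b == n or is_cut(b)):
                continue
            internal = sum(1 for i in range(a + 1, b) if is_cut(i))
            if internal > params.max_missed_cleavages:
                continue
            if not params._length_ok(b - a):
                continue
            sub = seq[a:b]
            if params.drop_ambiguous and any(c in AMBIGUOUS_RESIDUES for c in sub):
                continue
            out[sub] += 1
    return out
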