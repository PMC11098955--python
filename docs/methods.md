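# Methods

## The accounting model

The pipeline treats a metaproteomics identification compendium as a set of
unique peptide sequences (deduplicated across studies; per-study tables are
kept for per-study rules) and a reference catalog as the union of one
representative proteome per species. Every statistic is a set operation
between these two objects after in-silico digestion:

* **Digestion.** Fully specific tryptic digestion: cleavage after K or R,
  by default also before proline (Trypsin/P, matching common search-engine
  in-silico digestion); peptides span at most `max_missed_cleavages`
  internal cleavage points and satisfy the length filters. Defaults:
  minimum length 7 residues, ≤2 missed cleavages, no maximum length, I/L
  kept distinct. The proline rule, a maximum length, and I/L equating are
  exposed as flags because upstream search engines differ. Peptides
  overlapping ambiguity residues (B, J, O, U, X, Z) are dropped from
  matching by default — exact string matching is undefined for them — while
  the parent proteins are kept and flagged. A species' peptide universe is
  the set of unique peptide sequences of its genome (within-genome
  deduplication); redundant counts are available for diagnostics.
* **Occurrence index.** An exact inverted index peptide → (proteins,
  genomes) over the whole catalog. All downstream stages are queries
  against this index, so matching conventions (I/L, ambiguity handling)
  are applied in exactly one place (`DigestionParams.key`).
* **Host filtering.** The host proteome is digested with identical
  parameters. Identified peptides found only in the host are excluded from
  all microbial statistics; peptides found in both host and catalog are
  retained (and reported as an overlap count); peptides found in neither
  are kept in totals but excluded from taxon statistics.
* **LCA.** Computed purely over the catalog's 7-rank lineage table as the
  deepest common prefix of the source genomes' lineages — no external
  taxonomy service, so assignment is deterministic and self-contained.
  Ties are impossible on a ranked ladder; genomes sharing no rank at all
  (different domains) yield an explicit "no shared rank" state. A
  `bacteria_only` flag restricts per-species tables to Bacteria while the
  assignment universe keeps all prokaryotes.
* **Coverage.** Peptide-level numerators deliberately include peptides
  whose LCA is above species rank whenever the sequence occurs in the
  species' universe (a shared peptide is evidence for every species that
  contains it), so numerators summed over species exceed the retained
  peptide count — a documented multiplicity, not double counting. CDS per
  species equals the protein count of the representative genome.
  Protein-level coverage bins are <5%, 5–10%, 10–20%, 20–50%, ≥50%,
  left-closed right-open except the last, so they partition [0,1]; the
  5–10% band is materialized explicitly so bin counts always sum to the
  species count.
* **Annotation rules.** Broad-missing (no ko and no GO) and strict
  COG-unknown (no COG family or categories exactly {S}) are independent
  flags, never merged. A head protein without an annotation record is
  treated as fully unannotated and logged. "Highly abundant" is a rank
  decile: per study, a protein's total intensity is the sum of the
  intensities of the groups it heads, and the top ceil(0.10 · n) proteins
  qualify; qualifying in any one study suffices. A cumulative-intensity
  share variant was considered and rejected as the default because the
  rank decile is the simplest reading of a "top 10%" rule; the choice is
  localized in one function if the alternative is wanted.
* **Functional distinctness.** A peptide found in one COG family *and* in
  unannotated proteins is classified functional-distinct to that family
  (any family evidence wins); these mixed cases are counted separately
  (`n_mixed_family_unannotated`) for transparency. The three classes
  partition the unique peptide set exactly, enforced as an invariant at
  construction.
* **Composition.** The peptide-side denominator at rank r is the peptides
  assignable at r or deeper; peptides with a shallower LCA are excluded
  from that rank's denominator (their count is carried alongside so the
  all-peptides denominator can be inspected). Top-N lists are ranked by
  count with lexicographic tie-break at the boundary, making overlap
  counts deterministic.

## Percentage presentation

All statistics are computed in full precision; presentation rounds
half-even on the exact decimal expansion (2 decimals for peptide-level
coverage, 1 decimal elsewhere). Multi-class splits of one total are
presented with every class except the largest rounded and the largest
class as the complement `100 − Σ(others)`, so printed splits always total
exactly 100% — the usual convention for class breakdowns.

## Synthetic study conditions

The generator emulates the *shape* of the real inputs with known ground
truth:

* **Sequences.** i.i.d. residues over the 20 standard amino acids, K and R
  at 1/18 each (combined cleavage-residue probability 1/9 → mean tryptic
  fragment length ≈ 9, realistic for tryptic digests), other residues
  uniform. Protein lengths geometric around `mean_protein_length`
  (default 300) with a floor of 30, guaranteeing at least one peptide ≥7
  residues in essentially every protein.
* **Taxonomy.** A complete 7-rank ladder with configurable branching
  (default 3 phyla × 2 families × 2 genera × 2 species = 24 species).
* **Sequence sharing.** Within each genus the first species donates
  `ortholog_share_rate` (default 0.2) of its proteins; sisters carry
  copies mutated at `ortholog_mutation_rate` (default 0.02) per residue.
  This creates shared vs genome-distinct peptides at known rates and is
  the only systematic source of peptide sharing; copies inherit the
  donor's COG family, so the functional-distinctness ground truth is
  known by construction.
* **Annotations.** The annotation unit is the ortholog group or private
  protein. With probability `annotation_missing_rate` (default 0.25) a
  unit has no COG/ko/GO at all; with probability `cog_s_rate` (default
  0.09) it carries a dedicated unknown-function family with category S
  (and a generic ko, so the realized no-ko-and-no-GO fraction tracks the
  missing rate alone and the two rates stay orthogonal); otherwise a
  unit-unique family, category letter(s), ko and GO term.
* **Identifications.** One Dirichlet draw with concentration
  `abundance_skew` (default 0.3 — a strongly uneven community, as real
  gut communities are) sets per-species sampling weights shared across 3
  synthetic studies; each of `n_identified_peptides` draws (default
  20,000) picks a host peptide with probability `host_fraction` (default
  0.05) or a uniform peptide from the drawn species' universe, with
  log-normal intensities. Per study, each sampled microbial peptide
  yields a protein group containing every catalog protein with that
  peptide, sorted by ID; the head protein is the first member, and
  identical member lists are merged with summed intensity.
* **Determinism.** Each generation stage uses its own seeded RNG stream;
  identical seed + config give byte-identical files.

**What the synthetic conditions do not show.** Random sequences carry no
homology beyond the planted ortholog copies, so cross-genus and
cross-family peptide sharing is essentially absent (the shared-multi-family
class is near 0%, against 1.3% in real catalogs), LCAs above genus are
rare, and host/catalog peptide overlap is empty rather than small. There
is no model of peptide detectability, intensity-dependent missingness, or
FDR: passing tests demonstrate the correctness of the accounting, not the
biology of real identification rates.

## Problem sizes

Unit tests run at the default 24 × 100-protein scale (seconds). The
parameter-recovery suite and the acceptance script use 24 × 420 = 10,080
proteins and 50,000 sampled identifications (three seeds for recovery),
sizes at which binomial tolerances of ±1.5 percentage points are ≈3σ for
the recovered rates. Recovery is asserted against the configured rates
(annotation missingness, host fraction) and against the ledger (the
realized dominant species of the sample, exact host-only set equality).
The brute-force digestion oracle is O(n³) and is exercised on ≥1,000
random sequences of length ≤60 across a parameter grid; the LCA oracle is
checked exhaustively on a complete smaller catalog (10 proteins/genome,
mean length 120).

## Known limitations

* LCA uses the catalog lineage table only; no NCBI/GTDB service lookup or
  name reconciliation.
* Protein groups are simulated one-per-peptide; real protein inference
  (Occam's-razor grouping across peptides) produces coarser groups. Head
  protein extraction and all downstream accounting are agnostic to this.
* The full-scale replication against a real genome catalog and peptide
  compendium requires large downloads and is out of scope here; the
  genome-ID parsing rule (`GENOME_PROTEINIDX` by default) and the
  proline/max-length/IL digestion flags are the knobs to sweep when
  pinning printed catalog-scale numbers.
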