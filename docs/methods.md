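# Methods

## Pipeline

Given an assembly and a lineage dataset, the assessment runs four stages:

1. **Alignment.** The lineage's member proteins are aligned to the
   assembly by a spliced, frameshift-aware protein-to-genome aligner, or a
   pre-computed PAF stream is ingested. Alignments are parsed into records
   with 0-based half-open coordinates and an extended CIGAR over
   `{M, I, D, F, G, N, U, V}`.
2. **Translation and identity.** Each aligned locus's translation is
   reconstructed by walking the CIGAR over the genome (introns excised,
   split codons rejoined across U/V junctions, frameshifted G codons
   emitted as `X`, ambiguous codons as `X`, minus strands
   reverse-complemented first). Identity is computed over aligned residue
   columns only — M/U/V columns plus G columns, which count in the
   denominator but can never be identical, since a broken reading frame is
   evidence of error, not conservation. Insertions, deletions and introns
   contribute no columns. When a `cs` difference string is present it is
   used directly; both routes agree exactly on generated fixtures.
3. **Orthology filtration.** Every locus is scored independently against
   its group's profile HMM; loci with full-sequence bit score below the
   group's cutoff are discarded. The member protein with the highest bit
   score represents the group, and only its loci reach classification.
4. **Classification and reporting.** Missing / Fragmented / Single /
   Duplicated per the rules in the README, then dataset-level counts,
   percentages, mean identity, the frameshift-gene fraction and the
   divergence flag.

## CIGAR dialect

Op lengths are amino acids for M/I/D and nucleotides for F/G/N/U/V.
Consumption rules (pinned by property tests):

* target nucleotides: `3·M + 3·D + F + G + N + U + V` = target span;
* query amino acids: `ΣM + ΣI + #G + #U + #V` = query span;
* translation length: `ΣM + #G + #U + #V`.

U (phase-1) and V (phase-2) intron ops include the split codon's
nucleotides on both sides of the junction (1+intron+2 and 2+intron+1
respectively) and contribute the rejoined codon's single residue. A
*frameshift event* is one F or G operation, regardless of length; the
per-gene count, not the summed lengths, is reported.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| secondary-score ratio (`--outs`) | 0.97 | fraction of the query's best alignment score | alignments scoring below it are suppressed by the aligner; suppressed hits resurface if their better locus is removed |
| score cutoff boundary | ≥ cutoff | bits | matches conventional use of lineage cutoff files; pinned by a boundary test (99.9 fails a cutoff of 100, 100.0 passes) |
| length threshold | max(0, μ − 2σ) | amino acids | μ, σ from the lineage's `lengths_cutoff` (columns: group, 0, σ, μ); aligned length is ΣM, not genomic span |
| locus-overlap fraction | 0.5 | fraction of the shorter genomic span | same-contig, same-strand records overlapping more than this collapse to one locus, so redundant secondary records cannot fake a duplication |
| divergence floor | 0.5 | mean identity | strictly below 50% triggers a warning recommending a complementary gene-predictor-based assessment |

Bit scores are full-sequence scores, not best-domain or E-values: the
cutoff files are bit-valued and bit scores are independent of database
size. The in-process HMMER pipeline runs with the heuristic acceleration
filters disabled so short genuine fragments are scored rather than dropped;
the external `hmmsearch` backend passes `--max` for the same reason, and
the two agree to within rounding on fixtures.

## Design choices where the design was open

* **Duplication counts loci of the representative protein only**,
  consistent with the representative rule; loci of other member proteins
  never affect the status.
* **Fragmented requires *all* surviving loci below threshold**; one
  full-length locus makes the gene complete even if fragments co-exist.
  Consequently two surviving loci with only one full length are
  Duplicated.
* **Ties** in representative selection break to the lexicographically
  smallest protein id; locus deduplication keeps the higher-scoring
  record. Both choices are arbitrary but deterministic across platforms.
* **Only the sequence-level bit-score cutoff is applied**; per-domain
  cutoffs some lineage files also carry are not consulted.
* **Mean identity averages the representative's best-locus identity over
  non-missing groups.** With no surviving alignments at all the mean is
  undefined: no divergence warning is raised and an explicit note is
  recorded instead.
* **Missing cutoff entries fail open**: a group absent from
  `scores_cutoff` gets cutoff 0 (HMM scoring still runs), one absent from
  `lengths_cutoff` gets a degenerate threshold of 0 (never fragmented);
  both are warned about and collected on the dataset record.
* **Percentage rounding** is one decimal, half away from zero, applied
  only at presentation; internal values are never rounded.

## The synthetic-data generator

Toy lineages draw random peptides (80–120 aa by default), derive members
as 4%-substituted variants (a gap-free MSA), and build real profile HMMs
from them. Cutoffs are calibrated per group midway between the weakest
genuine signal — the members and a 30%-length fragment, so that fragmented
genes still pass the HMM stage — and the strongest of three shuffled
decoys, with the separation asserted. Genomes are built by
reverse-translating member peptides with uniform synonymous codons,
inserting canonical GT–AG introns (≥ 10 nt, any phase), applying defects
(extra exact copies, 3′ truncation, omission, 1-nt insertions/deletions as
F/G ops, substitutions, diverged paralog copies with an exact substitution
count so their score ratio to the primary locus is strictly below the
secondary cutoff), and embedding loci in random intergenic sequence
(200 nt, GC 0.4). The rendered PAF is exactly what an error-free aligner
would emit, including the secondary-suppression rule applied across each
query's loci.

What this does *not* emulate: repeats, pseudogenes, GC isochores,
alignment errors, non-canonical splice sites, alternative splicing. Tests
passing on these fixtures therefore establish the correctness of the
bookkeeping downstream of alignment — parsing, translation, scoring,
filtering, classification, reporting — not aligner robustness on real
genomes. The optional score-table backend goes one step further and
replaces HMM scoring with a labelled rule (pass iff planted identity
≥ 0.6); it exercises plumbing only and is never used where a real score
matters.

## Problem sizes

The test suite and the acceptance script run on toy lineages of 10 and 40
groups, 3 member proteins each, with scenarios of 8–40 planted genes —
sizes at which profile-HMM construction and scoring complete in seconds
while still covering every status, strand, intron phase and defect type.
Real lineages (thousands of groups, multi-GB downloads) and live aligner
runs use the identical code paths via `fetch_lineage` and `run_aligner`.

## Known limitations

* Sensitivity to distant homologs is bounded by one alignment round; the
  divergence warning exists precisely because sub-50%-identity assemblies
  need a complementary assessment.
* GFF-mode aligner output is not parsed (PAF dialect only).
* Lineage layouts predating the v5 odb10 format are unsupported.
* The aligner's exact scoring function is treated as an external contract;
  fixture scores (2 × identical columns) reproduce only its ranking
  behaviour, which is all the secondary-suppression rule needs.
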