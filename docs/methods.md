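# Methods

## Overview

`viroquant` profiles the viral fraction of multi-sample shotgun metagenomes.
Each sample passes through an identical protocol — quality trimming, pair
interlacing, subsampling, de novo contig construction, candidate-virus
identification — and then, crucially, *all* samples are re-quantified
against the **union** of every candidate reference observed in any sample.
This makes abundance columns comparable across samples: a virus detected
only in sample B still has a (possibly zero) row in sample A, the same way
an OTU table covers every taxon for every sample.

The second core idea is **fractional score splitting**. Virus reference
collections contain many near-identical isolates, so a read frequently maps
equally well to several references. Instead of picking one arbitrarily, a
read matching m references at the exact top score contributes weight 1/m to
each. Abundance then *expresses* assignment ambiguity: a block of related
references sharing a sample's reads signals "similar to many isolates,
identical to none", while rollups to genus or family re-concentrate the
weight and hide the sub-species uncertainty, as they should.

## Pipeline stages and parameters

### Quality control

Trimming is a 3' sliding-window rule: the read end is shrunk while the mean
Phred quality of the trailing width-4 window is below `qc.quality_threshold`
(default 20), then remaining trailing bases individually below the
threshold are stripped; the two phases alternate to a fixpoint, which makes
trimming idempotent. Reads shorter than `qc.min_length` (default 50) after
trimming, or with more than 10% N, are rejected. Rejection is a value, not
an error: a read whose mate was rejected continues as an orphan.

Subsampling applies **only to assembly input**: a uniform draw without
replacement of `round(0.75 * n)` reads, capped at 1,000,000 per sample
(`subsample.fraction`, `subsample.cap`), order-preserving and deterministic
per seed. Rounding is half-away-from-zero for cross-language determinism.
The full QC-passed read set is retained for remapping, so quantification
never loses depth to the assembly budget.

### Assembly

The built-in assembler is a naive canonical-k-mer de Bruijn unitig builder
(`assembly.k` default 31, odd so no k-mer equals its own reverse
complement). k-mers seen once are dropped as probable errors
(`assembly.min_kmer_count`, default 2) unless the input is tiny (< 100
reads), where everything is kept so toy runs assemble losslessly. Contigs
are maximal non-branching paths; adjacency is membership-based (does the
neighbouring k-mer exist?) rather than edge-based, which can conservatively
split a genuine path where an unrelated k-mer collides, but never joins
sequences that share no k-mer. A candidate step onto the current node's own
reverse complement is excluded as a self-loop artifact. Output from any
external assembler can be substituted via `--contigs FILE.fasta`; the
built-in builder exists to make the downstream stages testable end to end.

Reads contributing no k-mer to any contig are orphan singletons and are
classified individually, so low-coverage viruses that fail to assemble
still nominate candidates.

### Candidate identification and remapping

The native mapper is an **exact ungapped aligner**: for each reference and
strand it scores *every* placement of the query (score = number of matching
bases; N never matches) and keeps the reference's best placement, reported
as a hit if the score reaches `quantify.min_score` (default 60, sized for
~100 bp reads). Exactness matters because tie splitting is defined on exact
score equality: two references carrying a region verbatim must receive
provably identical scores. The scan is vectorised as a one-hot matrix
product (reads x reference windows), so desk-scale inputs map in seconds.
A seeded (k-mer indexed) mapper was deliberately not used: seeding can miss
the maximal-match placement once mismatches are dense, which would break
both the tie semantics and the mapper's exhaustive-oracle equivalence that
the test suite enforces.

Candidate identification maps contigs and singletons against the reference
database and takes each query's best-scoring subjects (within
`quantify.tie_tolerance`, default 0; hits above `quantify.evalue_cutoff`,
default 1e-5, are ignored when hits come from BLAST tabular input).
Candidates must additionally reach `quantify.min_identity` (default 60% of
the aligned window): an absolute score floor alone cannot separate a
multi-kilobase contig's chance matches — which grow linearly with length,
~25% of the window on random sequence — from real homology. A contig's hit
contributes its subjects to the candidate set only; reads earn their own
assignments at remap time, so contig chimeras cannot inflate counts.

After the union is formed, every QC-passed read of every sample is remapped
against the union references. Reads are assigned weight 1/m across their m
top-scoring references; reads with no qualifying hit flow to the
dark-matter stage. Abundance cells are accumulated in exact rational
arithmetic (each read adds 1/m), so a sample's column sum equals its
assigned-read count to within one float rounding per cell — the
conservation law the test suite asserts at 1e-12. Externally produced
remaps can be ingested from a minimal SAM subset (ties = records sharing
the maximal alignment score; unmapped flag = unassigned) or BLAST outfmt 6.

### Dark matter

Virus-unassigned reads are filtered in two sequential steps with the same
mapper and `min_score`: first against ribosomal references (16S/23S/5S
treated as one step), then against a human reference; the remainder is the
dark matter. The order matters only for the ribosomal/human split of
dual-matching reads — the dark count is order-invariant, and the
viral+ribosomal+human+dark counts always tile the QC-passed reads exactly
(an internal consistency check that raises if violated). Bacterial
*genomic* reads are deliberately not filtered: they may carry dormant
prophages, so they end in the dark set rather than being dropped. Both
filter steps are optional (`darkmatter.enable_rrna`, `enable_human`).

### Reference database

The database builder merges FASTA sources (first occurrence wins on
duplicate accessions) and clusters greedily at an identity threshold
(default 0.97): sequences are visited longest-first (accession-lexicographic
tie-break, so clustering is deterministic), each joining the first cluster
whose representative it matches at or above the threshold, else founding a
new cluster. Identity is the number of matched positions in a global
alignment that maximises matches (match +1, mismatch and gap 0) divided by
the shorter sequence's length. Membership is decided against
representatives only. Two consequences of the free-gap scoring are worth
knowing: unrelated random sequences align near their longest common
subsequence (~0.8 identity), so meaningful thresholds sit above that; and
no shared-k-mer count lower-bounds the achievable identity (insertions can
destroy every k-mer while preserving all matches), so there is no
prescreen — every candidate pair is aligned, which is fine at desk scale.
Per-source clustering before the joint pass is available (`--per-source`).

### Diversity and reporting

Alpha diversity is Shannon entropy H = -sum p_i ln p_i in nats, computed by
default on species-rank proportions (rank configurable); richness is the
count of taxa with positive weight. Population profiles sum member-sample
columns per group, roll up to the requested rank and normalise; regrouping
recomputes profiles from the *same* abundance table without
re-quantification. Heatmap orderings use log10(x+1)-transformed values,
Euclidean distance and average linkage — a conventional, reproducible
choice; the linkage trees are returned for external plotting.

### Benchmark evaluation

Given per-read assignments and truth labels, metrics are computed per rank
from raw counts (micro-averaged), never from pre-rounded percentages. Mates
sharing a pair id are merged (weights summed) so each truth row is
evaluated once. A read's call at a rank is its weight-majority label after
rolling fractional weights through the lineage; an exact tie between
*different* labels is ambiguous — assigned but incorrect — while ties
among references of the same higher-rank taxon merge into a single correct
label, preserving the point of score splitting. Reads are assignable at a
rank if their truth class is viral with a defined label there;
precision = correct/assigned, recall = correct/assignable, F = 2PR/(P+R),
and unclassified% is the assignable share without a resolving call. With
zero assigned reads precision is undefined and reported as 0 with a
`degenerate` flag.

## The synthetic community

The generator emulates a host-dominated virome sequencing run: 94.5% human
/ 4.8% bacterial / 0.7% viral read pairs by default, 100 bp paired ends
with fragment length ~ N(300, 25), constant Q30 qualities (an optional 3'
decay profile exercises the trimmer) and substitution-only errors (default
rate 0, so reads are exact substrings and the ungapped mapper's oracle
stays exact). Class counts are apportioned by the largest-remainder rule,
so realised compositions match the requested fractions exactly and
deterministically; a multinomial switch restores sampling. Viral reads are
spread over 5 synthetic genomes (2 kb, i.i.d.-uniform DNA) carrying a full
synthetic lineage (genome-type group, family, genus, species); bacterial
reads split between standalone rRNA gene records and a genomic reference
(`rrna_fraction`, default 0.5); a `mutate` helper creates isolates at an
exact substitution divergence for clustering and ambiguity tests.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: genome repeats and shared ancestry (uniform
random references make cross-mapping between unrelated sequences
essentially impossible, so real-world false assignment rates are higher),
indels and structured error profiles, coverage bias, and rRNA genes
embedded in their genomic context (the rRNA records are standalone so truth
labels stay exact).

## Numerical and determinism choices

- All randomness flows from one base seed through `derive_seed(seed,
  *tokens)` (CRC32-mixed, < 2^31); per-sample seeds depend on the sample id,
  not the processing order, so sample order never changes results.
- Strand ties in mapping prefer '+'; placement ties take the leftmost
  offset. Cluster ordering ties break lexicographically. Contigs are
  reported in canonical orientation (lexicographic min of the two strands),
  sorted longest-first.
- Abundance accumulation uses `fractions.Fraction`; weights are converted
  to float only at table construction.
- Degenerate inputs: empty FASTQ streams, empty reference sets, all-zero
  abundance columns and samples failing QC entirely are all defined
  (flagged or empty outputs), not errors; an all-zero vector passed to
  `shannon` is an error because its distribution is undefined.

## Problem sizes used in the checks

The bundled verification runs are sized for a laptop: reference genomes of
2 kb, samples of 120-1,000 read pairs for behavioural checks, and a
10,000-read run for abundance recovery (5 genomes at proportions
0.40/0.30/0.15/0.10/0.05, recovered within ±0.02 absolute). The subsampling
policy is exercised at its native scale (2,500,000-element draws) since it
is O(n) and cheap.

## Known limitations

- The unitig assembler has no error correction beyond singleton-k-mer
  dropping and no paired-end awareness; it is a testing substitute, and
  real studies should feed external assemblies through `--contigs`.
- The exact mapper is ungapped; indel-containing reads lose score linearly
  with displacement. E-values are only meaningful for ingested BLAST hits
  (native hits carry evalue 0).
- Greedy clustering is quadratic in the number of input sequences in the
  worst case (no prescreen is sound under free-gap identity; see above).
- Benchmark metrics evaluate the viral class per rank; host/bacterial
  classes are summarised by the read-distribution report instead.
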