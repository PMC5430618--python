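# viroquant

Multi-sample virome profiling at desk scale: quantify known viruses across
shotgun metagenome samples, extract the unassigned "dark matter", and
report diversity and benchmark metrics — all runnable offline on a laptop,
with a bundled labelled-community simulator.

## Who this is for

Virome studies sequence everything in a sample; known viruses are typically
a sliver of the reads, buried under host and bacterial background, and the
reference collections used to identify them contain many near-identical
isolates of every relevant serotype. `viroquant` is for analysts who need
per-sample virus abundance tables that are (a) comparable **across**
samples and (b) honest about assignment ambiguity — plus the leftover reads
that matched nothing, which is where novel viruses hide.

## The method

Every sample runs the identical protocol: quality trimming → pair
interlacing → subsampling (assembly input only; default 75% of reads,
capped at 1,000,000) → de novo contig construction → candidate virus
identification from contigs and orphan singleton reads. Then two ideas do
the real work:

1. **Union remapping.** The candidate reference sets of *all* samples are
   unioned, and every sample's full QC-passed read set is remapped against
   that union. A virus observed only in sample B therefore has a row
   (possibly zero) in sample A — the abundance table behaves like an OTU
   table, cross-sample comparable by construction.

2. **Fractional score splitting.** A read matching m references equally
   well (exact top-score tie) contributes weight 1/m to each:

       w(read, ref) = 1/m   for each of the m tied best references,

   so each assigned read contributes total weight 1, and a sample's column
   sums to its assigned-read count exactly. Ambiguity between isolates
   shows up as weight spread across a block of related references instead
   of an arbitrary winner; rollups to genus or family re-concentrate it.

Virus-unassigned reads are then filtered sequentially — ribosomal
references (16S/23S/5S) first, then a human reference — and the remainder
is reported as dark matter. Bacterial *genomic* reads are deliberately kept
(dormant prophages), landing in the dark set rather than being dropped.
Reports include per-sample Shannon alpha diversity (H = −Σ pᵢ ln pᵢ, nats),
group-level population profiles with dynamic regrouping, hierarchical
clustering orderings for heatmaps, and per-rank precision/recall/F against
truth labels. A greedy identity-threshold clusterer (97% default) builds
the reduced reference database.

See `docs/methods.md` for parameters, numerical conventions and known
limitations.

## Worked example

Simulate two gut-like samples against the same synthetic references, run
the pipeline, and benchmark one sample against its truth labels:

```
viroquant --seed 5 simulate --config simA.yaml --out simA --sample-id gutA
viroquant --seed 5 simulate --config simB.yaml --out simB --sample-id gutB
viroquant --seed 5 run --manifest manifest.tsv --config run.yaml --out out
```

where `simA.yaml` requests 1,000 read pairs at 90/5/5% human/bacterial/viral
with viral proportions (0.5, 0.3, 0.2, 0, 0), `simB.yaml` 93/4/3% with
(0, 0, 0.4, 0.4, 0.2), and `manifest.tsv` lists each sample's R1/R2 FASTQ.
`out/abundance.tsv` then contains:

```
accession  group  family          genus          species          gutA   gutB
VREF_001   dsDNA  Synthfamily_01  Synthgenus_01  Synthspecies_01  50.0   0.0
VREF_002   dsDNA  Synthfamily_01  Synthgenus_01  Synthspecies_02  30.0   0.0
VREF_003   dsDNA  Synthfamily_01  Synthgenus_02  Synthspecies_03  20.0   24.0
VREF_004   dsDNA  Synthfamily_01  Synthgenus_02  Synthspecies_04   0.0   24.0
VREF_005   ssRNA  Synthfamily_02  Synthgenus_03  Synthspecies_05   0.0   12.0
```

Each cell is summed read weights: gutA's 50 viral read pairs (100 reads)
split 50/30/20 across its three viruses, and the union gives gutA explicit
zero rows for gutB-only viruses (and vice versa). The read-distribution
report (`out/read_distribution.tsv`) partitions every QC-passed read:

```
sample_id  viral  ribosomal  human  dark  total
gutA       100    50         1800   50    2000
gutB       60     40         1860   40    2000
```

— here the dark reads are exactly the simulated bacterial genomic reads,
kept rather than filtered. Diversity (`out/diversity.tsv`) reports Shannon
entropy over species proportions: gutA's (0.5, 0.3, 0.2) profile gives
H = 1.030 nats, richness 3. Finally,

```
viroquant benchmark --assignments out/read_assignments.tsv \
    --truth simB/truth.tsv --lineage simA/lineage.tsv --ranks genus,species
genus: precision 100.00% recall 100.00% F 100.00% (assigned 30/30)
species: precision 100.00% recall 100.00% F 100.00% (assigned 30/30)
```

— with error-free reads and non-overlapping references, every one of
gutB's 30 viral read pairs resolves to its true species.

Other subcommands: `makedb` (merge + cluster reference FASTAs), `quantify`
(one sample directly against a FASTA), `darkmatter` (partition a FASTQ),
`report` (diversity/profiles/orderings from an existing abundance table).

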