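"""Synthetic labelled metagenome generator.

Emulates a mixed shotgun-sequencing community — an overwhelming host (human)
background, a bacterial slice split between ribosomal genes and genomic DNA,
and a small viral fraction spread over several genomes — with a per-read
truth table, so every pipeline stage can be tested without any download.

Defaults mirror the benchmark community the pipeline is evaluated on:
94.5% human / 4.8% bacterial / 0.7% viral, 100 bp paired-end reads, and
error-free bases (substitution errors and a 3' quality-decay profile are
available to exercise trimming and mismatch tolerance). Class counts are
apportioned deterministically by the largest-remainder rule rather than
multinomial sampling, so realised compositions are exact; a multinomial
switch restores sampling for power-style experiments.

Reference sequences are i.i.d.-uniform DNA. Real genomes have repeats,
skewed composition and shared ancestry; uniform sequences make cross-mapping
between unrelated references essentially impossible, which is exactly what
makes truth labels exact (and what a pass here does *not* prove about real
data — see the methods note).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .benchmark import TruthRow, TruthTable
from .records import Lineage, LineageTable, ReadRecord, SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GROUPS = ("dsDNA", "ssRNA", "dsRNA")

DEFAULT_COMPOSITION = {"human": 0.945, "bacterial": 0.048, "viral": 0.007}


def derive_seed(base_seed: int, *tokens: str) -> int:
    """Stable sub-seed from a base seed and string tokens (< 2^31)."""
    h = zlib.crc32("/".join(tokens).encode()) & 0x7FFFFFFF
    return (base_seed * 1_000_003 + h) % (2**31 - 1)


def _uniform_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass
class ReferenceSet:
    """Labelled synthetic references for one simulated study."""

    viral: List[SequenceRecord]
    human: SequenceRecord
    bacterial: SequenceRecord
    rrna: List[SequenceRecord]
    lineage: LineageTable


def make_references(
    n_viral: int = 5,
    viral_length: int = 2000,
    human_length: int = 10_000,
    bacterial_length: int = 20_000,
    rrna_lengths: Sequence[int] = (1500, 2900, 120),
    seed: int = 0,
) -> ReferenceSet:
    """Generate labelled reference sequences and their lineage table.

    Viral genomes get synthetic species/genus/family/group labels (two
    species per genus, two genera per family, genome-type groups cycling) so
    rollup and benchmark logic exercise real taxonomic structure. The rRNA
    records stand for the 16S/23S/5S subtraction sets; they are independent
    sequences, not subsequences of the bacterial genome, so truth labels for
    the read partition are exact.
    """
    if viral_length < 200:
        raise ValueError("reference lengths must be >= 200")
    rng = np.random.Generator(np.random.PCG64(derive_seed(seed, "references")))
    lineage = LineageTable()
    viral = []
    for i in range(n_viral):
        acc = f"VREF_{i + 1:03d}"
        viral.append(
            SequenceRecord(acc, f"synthetic virus genome {i + 1}",
                           _uniform_dna(rng, viral_length))
        )
        lineage.add(
            acc,
            Lineage(
                group=_GROUPS[(i // 4) % len(_GROUPS)],
                family=f"Synthfamily_{i // 4 + 1:02d}",
                genus=f"Synthgenus_{i // 2 + 1:02d}",
                species=f"Synthspecies_{i + 1:02d}",
            ),
        )
    human = SequenceRecord("HUM_DECOY", "synthetic human-like decoy",
                           _uniform_dna(rng, human_length))
    bacterial = SequenceRecord("BACT_GENOME", "synthetic bacterial genome",
                               _uniform_dna(rng, bacterial_length))
    names = ("16S", "23S", "5S")
    rrna = [
        SequenceRecord(
            f"RRNA_{names[i % 3]}_{i + 1}",
            "synthetic ribosomal gene",
            _uniform_dna(rng, length),
        )
        for i, length in enumerate(rrna_lengths)
    ]
    return ReferenceSet(viral=viral, human=human, bacterial=bacterial,
                        rrna=rrna, lineage=lineage)


def mutate(seq: SequenceRecord, divergence: float, seed: int = 0) -> SequenceRecord:
    """Substitute exactly round(divergence * length) positions, each to a
    different base — near-identical isolates for clustering and ambiguity
    tests."""
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    n = len(seq)
    n_sub = int(math.floor(divergence * n + 0.5))
    rng = np.random.Generator(np.random.PCG64(derive_seed(seed, "mutate", seq.accession)))
    positions = rng.choice(n, size=n_sub, replace=False)
    residues = list(seq.residues)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != residues[pos]]
        residues[pos] = alternatives[rng.integers(len(alternatives))]
    return SequenceRecord(
        accession=f"{seq.accession}_mut",
        description=f"{seq.description} ({divergence:.3f} diverged)",
        residues="".join(residues),
    )


def largest_remainder(n: int, fractions: Mapping[str, float]) -> Dict[str, int]:
    """Hamilton apportionment of n items by fractional shares (exact and
    deterministic; ties on remainder break by key order)."""
    total_frac = sum(fractions.values())
    if abs(total_frac - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {total_frac}, expected 1")
    keys = list(fractions)
    floors = {k: int(math.floor(n * fractions[k])) for k in keys}
    remainder = n - sum(floors.values())
    by_frac = sorted(keys, key=lambda k: (-(n * fractions[k] - floors[k]), keys.index(k)))
    for k in by_frac[:remainder]:
        floors[k] += 1
    return floors


@dataclass
class SimConfig:
    """Study conditions for one simulated sample."""

    n_reads: int = 1000  # read pairs
    composition: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    read_length: int = 100
    error_rate: float = 0.0
    insert_mean: int = 300
    insert_sd: int = 25
    seed: int = 0
    viral_proportions: Optional[Sequence[float]] = None  # default: uniform
    rrna_fraction: float = 0.5  # share of bacterial reads drawn from rRNA genes
    multinomial: bool = False  # sample class counts instead of apportioning
    quality: int = 30
    quality_decay: bool = False  # linear 3' decay to exercise the trimmer

    def validate(self) -> None:
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.viral_proportions is not None:
            if abs(sum(self.viral_proportions) - 1.0) > 1e-9:
                raise ValueError("viral_proportions must sum to 1")


def _apply_errors(bases: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0:
        return bases
    out = list(bases)
    hits = np.nonzero(rng.random(len(out)) < error_rate)[0]
    for pos in hits:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def _quals(config: SimConfig, rng: np.random.Generator) -> List[int]:
    L = config.read_length
    if not config.quality_decay:
        return [config.quality] * L
    # linear decay over the final third of the read, down to Q2
    decay_start = 2 * L // 3
    quals = [config.quality] * decay_start
    span = L - decay_start
    for i in range(span):
        q = config.quality - (config.quality - 2) * (i + 1) // span
        quals.append(max(2, q))
    return quals


def simulate_reads(
    refs: ReferenceSet, config: SimConfig, sample_id: str = "S1"
) -> Tuple[List[Tuple[ReadRecord, ReadRecord]], TruthTable]:
    """Simulate paired-end reads with per-pair truth labels.

    Fragments are uniform over the chosen reference; R1 is the fragment's
    5' end, R2 the reverse complement of its 3' end. Substitution errors
    only (no indels), so an error-free read is an exact substring — or exact
    reverse-complement substring — of its source.
    """
    config.validate()
    rng = np.random.Generator(
        np.random.PCG64(derive_seed(config.seed, "reads", sample_id))
    )
    if config.multinomial:
        keys = list(config.composition)
        draws = rng.multinomial(config.n_reads, [config.composition[k] for k in keys])
        class_counts = dict(zip(keys, draws.tolist()))
    else:
        class_counts = largest_remainder(config.n_reads, config.composition)

    viral_props = config.viral_proportions
    if viral_props is None:
        n_v = len(refs.viral)
        viral_props = [1.0 / n_v] * n_v
    per_virus = largest_remainder(
        class_counts.get("viral", 0),
        {refs.viral[i].accession: p for i, p in enumerate(viral_props)},
    )
    n_bact = class_counts.get("bacterial", 0)
    bact_split = largest_remainder(
        n_bact, {"rrna": config.rrna_fraction, "genomic": 1 - config.rrna_fraction}
    ) if n_bact else {"rrna": 0, "genomic": 0}

    # (source record, truth class, origin) per pair, in a fixed class order
    plan: List[Tuple[SequenceRecord, str]] = []
    plan += [(refs.human, "human")] * class_counts.get("human", 0)
    for _ in range(bact_split["rrna"]):
        plan.append((refs.rrna[rng.integers(len(refs.rrna))], "bacterial"))
    plan += [(refs.bacterial, "bacterial")] * bact_split["genomic"]
    for virus in refs.viral:
        plan += [(virus, "viral")] * per_virus[virus.accession]

    pairs: List[Tuple[ReadRecord, ReadRecord]] = []
    truth = TruthTable()
    L = config.read_length
    for i, (source, cls) in enumerate(plan):
        ref_len = len(source)
        if L >= ref_len:
            raise ValueError(
                f"read_length {L} must be below reference length {ref_len} "
                f"({source.accession})"
            )
        frag_len = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        frag_len = max(L, min(frag_len, ref_len))
        start = int(rng.integers(0, ref_len - frag_len + 1))
        frag = source.residues[start : start + frag_len]
        read_id = f"{sample_id}_{cls[0]}{i + 1:06d}"
        r1_bases = _apply_errors(frag[:L], rng, config.error_rate)
        r2_bases = _apply_errors(revcomp(frag)[:L], rng, config.error_rate)
        pairs.append(
            (
                ReadRecord(read_id, 1, r1_bases, _quals(config, rng)),
                ReadRecord(read_id, 2, r2_bases, _quals(config, rng)),
            )
        )
        truth.add(
            TruthRow(
                read_id=read_id,
                cls=cls,
                lineage=refs.lineage.get(source.accession),
                origin=source.accession,
            )
        )
    return pairs, truth
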