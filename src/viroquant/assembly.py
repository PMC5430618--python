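"""Desk-scale de novo contig construction.

A naive de Bruijn unitig builder: reads are decomposed into canonical k-mers
(a k-mer and its reverse complement are the same node, so strand is handled
once, here), k-mers seen only once are dropped as likely sequencing errors,
and contigs are the maximal non-branching paths of the remaining graph.
Output from any external assembler can be substituted as a FASTA of contigs;
this builder exists so the downstream pipeline is testable end to end.

Reads not contributing a single k-mer to any contig are "orphan singletons"
and are classified individually alongside the contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

from .records import ReadRecord, canonical, revcomp

DEFAULT_K = 31
TINY_INPUT_READS = 100  # below this, singleton k-mers are kept


@dataclass(slots=True)
class Contig:
    contig_id: str
    residues: str
    read_support: int

    def __len__(self) -> int:
        return len(self.residues)


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            yield km


def _solid_kmers(
    reads: Sequence[ReadRecord], k: int, min_count: int
) -> Set[str]:
    counts: Dict[str, int] = {}
    for read in reads:
        for km in _kmers(read.bases.upper(), k):
            ck = canonical(km)
            counts[ck] = counts.get(ck, 0) + 1
    return {km for km, c in counts.items() if c >= min_count}


def _right_extensions(kmer: str, solid: Set[str]) -> List[str]:
    """Oriented k-mers reachable by appending one base (solid only).

    A candidate landing on the current node itself (its reverse complement
    shares the canonical form) is a self-loop artifact of membership-based
    adjacency, not a real overlap; it is excluded.
    """
    suffix = kmer[1:]
    own = canonical(kmer)
    return [
        suffix + b
        for b in "ACGT"
        if canonical(suffix + b) in solid and canonical(suffix + b) != own
    ]


def _left_extensions(kmer: str, solid: Set[str]) -> List[str]:
    prefix = kmer[:-1]
    own = canonical(kmer)
    return [
        b + prefix
        for b in "ACGT"
        if canonical(b + prefix) in solid and canonical(b + prefix) != own
    ]


def _extend_right(contig: str, k: int, solid: Set[str], used: Set[str]) -> str:
    """Walk right from an oriented contig's last k-mer through
    non-branching nodes."""
    current = contig[-k:]
    while True:
        nexts = _right_extensions(current, solid)
        if len(nexts) != 1:
            break
        nxt = nexts[0]
        if canonical(nxt) in used:
            break  # already consumed (cycle or met another unitig)
        # the step is non-branching only if nxt's sole left-extension is us
        backs = _left_extensions(nxt, solid)
        if len(backs) != 1:
            break
        contig += nxt[-1]
        current = nxt
        used.add(canonical(nxt))
    return contig


def build_unitigs(
    reads: Sequence[ReadRecord],
    k: int = DEFAULT_K,
    min_kmer_count: Optional[int] = None,
) -> List[Contig]:
    """Maximal non-branching paths of the canonical de Bruijn graph.

    ``min_kmer_count`` defaults to 2 (drop likely-error k-mers) unless the
    input is tiny (< 100 reads), where every k-mer is kept so small tests and
    toy runs assemble losslessly.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical k-mers require no palindromes)")
    if reads and k >= min(len(r) for r in reads):
        raise ValueError("k must be smaller than the shortest read")
    if min_kmer_count is None:
        min_kmer_count = 1 if len(reads) < TINY_INPUT_READS else 2
    solid = _solid_kmers(reads, k, min_kmer_count)
    used: Set[str] = set()
    raw: List[str] = []
    for seed in sorted(solid):  # sorted iteration fixes determinism
        if seed in used:
            continue
        used.add(seed)
        right = _extend_right(seed, k, solid, used)
        # extend left = extend right on the reverse complement
        full = revcomp(_extend_right(revcomp(right), k, solid, used))
        raw.append(min(full, revcomp(full)))  # canonical orientation
    raw.sort(key=lambda s: (-len(s), s))
    contig_kmers: Dict[str, int] = {}
    contigs: List[Contig] = []
    for i, seq in enumerate(raw):
        cid = f"contig_{i + 1:05d}"
        contigs.append(Contig(contig_id=cid, residues=seq, read_support=0))
        for km in _kmers(seq, k):
            contig_kmers.setdefault(canonical(km), i)
    # read support: number of reads sharing >= 1 k-mer with the contig
    for read in reads:
        touched = set()
        for km in _kmers(read.bases.upper(), k):
            idx = contig_kmers.get(canonical(km))
            if idx is not None:
                touched.add(idx)
        for idx in touched:
            contigs[idx].read_support += 1
    return [c for c in contigs if c.read_support >= 1]


def collect_singletons(
    reads: Sequence[ReadRecord], contigs: Sequence[Contig], k: int = DEFAULT_K
) -> List[ReadRecord]:
    """Reads none of whose canonical k-mers occur in any contig.

    These orphan reads are classified individually: a read too divergent (or
    too low-coverage) to assemble can still identify a candidate virus.
    """
    contig_kmers: Set[str] = set()
    for contig in contigs:
        for km in _kmers(contig.residues.upper(), k):
            contig_kmers.add(canonical(km))
    singles: List[ReadRecord] = []
    for read in reads:
        if not any(
            canonical(km) in contig_kmers for km in _kmers(read.bases.upper(), k)
        ):
            singles.append(read)
    return singles
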