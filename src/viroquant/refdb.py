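"""Reference virus database construction.

Merges FASTA sources (first occurrence wins on duplicate accessions) and
reduces redundancy by greedy identity-threshold clustering, the CD-HIT-style
strategy: sequences are visited longest-first and each joins the first
existing cluster whose *representative* it matches at or above the identity
threshold, otherwise it founds a new cluster. With the conventional 97%
threshold this collapses near-identical virus isolates onto one
representative, trading serotype-level resolution for a database against
which ambiguous read assignment stays interpretable.

Identity between two sequences is the number of matched positions in a
global alignment that maximises matches (match +1, mismatch/gap 0), divided
by the length of the shorter sequence — the CD-HIT denominator convention.
Every candidate pair is aligned; because gaps are free under this scoring, a
shared-k-mer screen has no sound lower bound and is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import Align

from .records import SequenceRecord

DEFAULT_IDENTITY = 0.97


@dataclass
class Cluster:
    """One identity cluster: a representative and its members with their
    identity to the representative (the representative itself at 1.0)."""

    representative: str
    members: List[Tuple[str, float]] = field(default_factory=list)


@dataclass
class MergeResult:
    records: List[SequenceRecord]
    duplicates_dropped: int


def merge_sources(sources: Sequence[Iterable[SequenceRecord]]) -> MergeResult:
    """Union of several FASTA sources keyed by accession; the first
    occurrence of a duplicated accession wins and later ones are counted."""
    if len(sources) < 1:
        raise ValueError("at least one source required")
    merged: Dict[str, SequenceRecord] = {}
    dropped = 0
    for source in sources:
        for rec in source:
            if rec.accession in merged:
                dropped += 1
            else:
                merged[rec.accession] = rec
    return MergeResult(records=list(merged.values()), duplicates_dropped=dropped)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = 0
    a.extend_gap_score = 0
    return a


_ALIGNER = _aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of the shorter sequence matched in a matches-maximising
    global alignment. Symmetric; 1.0 for identical sequences."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compute identity of an empty sequence")
    matches = _ALIGNER.score(a.residues, b.residues)
    return float(matches) / min(len(a), len(b))


def greedy_cluster(
    seqs: Sequence[SequenceRecord],
    threshold: float = DEFAULT_IDENTITY,
) -> List[Cluster]:
    """Greedy longest-first clustering at an identity threshold.

    Ties in length break on accession lexicographic order, so the clustering
    is deterministic. Representatives are returned in founding order; each
    representative has identity < threshold to every earlier representative.
    Membership is decided against representatives only (no all-pairs check
    within a cluster), matching the greedy algorithm's contract.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda s: (-len(s), s.accession))
    clusters: List[Cluster] = []
    reps: List[SequenceRecord] = []
    for seq in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            ident = pairwise_identity(seq, rep)
            if ident >= threshold:
                cluster.members.append((seq.accession, ident))
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative=seq.accession, members=[(seq.accession, 1.0)])
            )
            reps.append(seq)
    return clusters


def representatives(
    clusters: Sequence[Cluster], records: Sequence[SequenceRecord]
) -> List[SequenceRecord]:
    """Representative records in founding order."""
    by_acc = {rec.accession: rec for rec in records}
    return [by_acc[c.representative] for c in clusters]
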