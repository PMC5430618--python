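"""Viral dark-matter extraction.

Reads that match no known virus are filtered sequentially: first against
ribosomal DNA (16S/23S/5S, treated as one step), then against a human
reference. What survives is the "dark matter" — candidate novel viruses.
The subtraction order matters for the ribosomal/human split of dual-matching
reads but never for the dark count. Bacterial *genomic* (non-rRNA) reads are
deliberately not filtered: they may carry dormant prophages, so they flow
into the dark set rather than being discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from . import quantify
from .records import ReadRecord, SequenceRecord


@dataclass(slots=True)
class ReadDistribution:
    """Per-sample partition of QC-passed reads into origins."""

    sample_id: str
    viral: int
    ribosomal: int
    human: int
    dark: int
    total: int

    def validate(self) -> None:
        if self.viral + self.ribosomal + self.human + self.dark != self.total:
            raise RuntimeError(
                f"read partition inconsistent for {self.sample_id}: "
                f"{self.viral}+{self.ribosomal}+{self.human}+{self.dark} "
                f"!= {self.total}"
            )

    def fractions(self) -> dict:
        t = self.total or 1
        return {
            "viral": self.viral / t,
            "ribosomal": self.ribosomal / t,
            "human": self.human / t,
            "dark": self.dark / t,
        }


def _matches_any(
    reads: Sequence[ReadRecord], refs: Sequence[SequenceRecord], min_score: int
) -> List[bool]:
    hit_lists = quantify.map_reads(reads, refs, min_score)
    return [bool(h) for h in hit_lists]


def partition_reads(
    unassigned: Sequence[ReadRecord],
    rrna_db: Sequence[SequenceRecord],
    human_ref: Sequence[SequenceRecord],
    min_score: int,
) -> Tuple[List[ReadRecord], List[ReadRecord], List[ReadRecord]]:
    """Split virus-unassigned reads into (ribosomal, human, dark).

    The matching criterion is the same exact ungapped mapper and min_score
    used for viral remapping. Empty reference sets are allowed — that step
    then assigns nothing. The three sets are disjoint and exhaustive.
    """
    ribosomal: List[ReadRecord] = []
    remainder: List[ReadRecord] = []
    for read, hit in zip(unassigned, _matches_any(unassigned, rrna_db, min_score)):
        (ribosomal if hit else remainder).append(read)
    human: List[ReadRecord] = []
    dark: List[ReadRecord] = []
    for read, hit in zip(remainder, _matches_any(remainder, human_ref, min_score)):
        (human if hit else dark).append(read)
    return ribosomal, human, dark


def distribution_report(
    sample_id: str,
    viral_count: int,
    ribosomal: Sequence[ReadRecord],
    human: Sequence[ReadRecord],
    dark: Sequence[ReadRecord],
) -> ReadDistribution:
    """Assemble and validate the per-sample read-origin partition."""
    dist = ReadDistribution(
        sample_id=sample_id,
        viral=viral_count,
        ribosomal=len(ribosomal),
        human=len(human),
        dark=len(dark),
        total=viral_count + len(ribosomal) + len(human) + len(dark),
    )
    dist.validate()
    return dist
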