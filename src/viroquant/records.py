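"""Domain record types shared across the pipeline.

The atomic units are :class:`ReadRecord` (one sequencing read),
:class:`SequenceRecord` (one reference sequence) and :class:`LineageTable`
(accession -> taxonomy). Everything downstream — QC, assembly, mapping,
partitioning — operates on these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence

UNKNOWN = "unknown"  # sentinel for missing taxonomy ranks; never the empty string

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form of a k-mer: lexicographic min of itself and its reverse
    complement. Fixes strand handling throughout assembly."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass(slots=True)
class ReadRecord:
    """One sequencing read.

    ``quals`` are Phred scores (integers), one per base. ``mate`` is 1 or 2
    and is inferred from file role (R1/R2), never parsed from headers.
    """

    read_id: str
    mate: int
    bases: str
    quals: List[int]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"read {self.read_id!r}: mate must be 1 or 2")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(slots=True)
class SequenceRecord:
    """A reference sequence (virus genome, rRNA gene, host decoy...)."""

    accession: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


class Lineage(NamedTuple):
    """Taxonomy labels for one reference. ``group`` is the top tier
    (Baltimore/genome-type, e.g. dsDNA); missing ranks carry the
    ``unknown`` sentinel."""

    group: str = UNKNOWN
    family: str = UNKNOWN
    genus: str = UNKNOWN
    species: str = UNKNOWN


RANKS = ("group", "family", "genus", "species")


@dataclass
class LineageTable:
    """Accession -> :class:`Lineage` mapping with sentinel-aware lookup."""

    entries: Dict[str, Lineage] = field(default_factory=dict)

    def add(self, accession: str, lineage: Lineage) -> None:
        if accession in self.entries:
            raise ValueError(f"duplicate accession in lineage table: {accession}")
        self.entries[accession] = lineage

    def get(self, accession: str) -> Lineage:
        """Lineage for an accession; all-sentinel if absent."""
        return self.entries.get(accession, Lineage())

    def label(self, accession: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown taxonomy rank {rank!r}; expected one of {RANKS}")
        return getattr(self.get(accession), rank)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def unique_accessions(records: Iterable[SequenceRecord]) -> None:
    """Raise if any accession repeats within a record set."""
    seen = set()
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession: {rec.accession}")
        seen.add(rec.accession)
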