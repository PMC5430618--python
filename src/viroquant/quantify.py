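"""Cross-sample viral quantification.

The heart of the pipeline: identify candidate references per sample, take the
union across all samples, remap every QC-passed read against that union, and
split each read's unit weight evenly among the references it matches equally
well. Summed fractional weights form the samples x references abundance table
(an OTU-table analogue), so assignment ambiguity between near-identical virus
isolates is expressed in the table instead of being resolved arbitrarily.

The native read mapper is an *exact* ungapped aligner: for every reference and
strand it scores every placement of the read (score = number of matching
bases) and reports the reference's best placement. Exactness keeps the
tie-splitting rule well defined — two references carrying the same region
verbatim receive provably identical scores. The scan is vectorised as a
one-hot matrix product, so desk-scale inputs (thousands of reads, kilobase
references) map in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import RANKS, Lineage, LineageTable, ReadRecord, SequenceRecord, revcomp

__all__ = [
    "AlignmentHit",
    "ReadAssignment",
    "AbundanceTable",
    "best_hits",
    "candidate_union",
    "kmer_map",
    "map_reads",
    "map_sequence",
    "assign_read",
    "abundance_table",
    "rollup",
    "assignments_from_sam",
]


@dataclass(slots=True)
class AlignmentHit:
    """One query -> reference match.

    Common currency between the native mapper and parsed external formats
    (BLAST outfmt 6, minimal SAM). Coordinates are 1-based inclusive;
    a minus-strand hit carries ``s_start > s_end``.
    """

    query_id: str
    subject: str
    identity: float  # percent, 0..100
    aligned_length: int
    score: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # '+' or '-'


@dataclass(slots=True)
class ReadAssignment:
    """Per-read fractional assignment: list of (accession, weight).

    Weights are 1/m for the m references tied at the best score and sum to
    one; an empty list means the read is unassigned (dark-matter candidate).
    """

    read_id: str
    weights: List[Tuple[str, float]]

    @property
    def assigned(self) -> bool:
        return bool(self.weights)


# ---------------------------------------------------------------------------
# best-hit selection and weight splitting
# ---------------------------------------------------------------------------


def best_hits(
    hits: Sequence[AlignmentHit],
    evalue_cutoff: float = math.inf,
    tie_tolerance: float = 0.0,
) -> set:
    """Subjects tied at the top score among hits passing the e-value cutoff.

    ``tie_tolerance`` widens "equally well" to scores within that margin of
    the maximum (default 0: exact ties only, the strict reading of splitting
    among best matches).
    """
    passing = [h for h in hits if h.evalue <= evalue_cutoff]
    if not passing:
        return set()
    top = max(h.score for h in passing)
    return {h.subject for h in passing if h.score >= top - tie_tolerance}


def assign_read(
    read_hits: Sequence[AlignmentHit],
    tie_tolerance: float = 0.0,
    evalue_cutoff: float = math.inf,
) -> ReadAssignment:
    """Split a read's unit weight evenly among its tied best references."""
    if read_hits:
        read_id = read_hits[0].query_id
    else:
        read_id = ""
    tied = sorted(best_hits(read_hits, evalue_cutoff, tie_tolerance))
    m = len(tied)
    if m == 0:
        return ReadAssignment(read_id=read_id, weights=[])
    w = 1.0 / m
    return ReadAssignment(read_id=read_id, weights=[(acc, w) for acc in tied])


def candidate_union(per_sample: Mapping[str, Iterable[str]]) -> List[str]:
    """Sorted union of per-sample candidate accession sets.

    The union is what every sample is remapped against, which makes abundance
    columns comparable across samples: a virus seen only in sample B still
    gets a row (possibly zero) in sample A.
    """
    if not per_sample:
        raise ValueError("candidate_union requires at least one sample")
    union: set = set()
    for accs in per_sample.values():
        union |= set(accs)
    return sorted(union)


# ---------------------------------------------------------------------------
# native exact ungapped mapper
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    """Bases to codes 0..3; N (and anything else) to 4, which one-hot
    encodes to all-zeros and therefore never matches."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_matrix(ref_codes: np.ndarray, read_len: int) -> Optional[np.ndarray]:
    """(4*L, P) matrix Y with Y[4*s+c, o] = 1 iff ref[o+s] == base c.

    Matching-base counts for all P = R-L+1 placements of a batch of reads X
    (one-hot, shape (n, 4*L)) are then the single product X @ Y.
    """
    L, R = read_len, len(ref_codes)
    P = R - L + 1
    if P <= 0:
        return None
    onehot = np.zeros((R, 4), dtype=np.float32)
    valid = ref_codes < 4
    onehot[np.arange(R)[valid], ref_codes[valid]] = 1.0
    # rows (s, c): slice I_c[s : s+P]
    win = np.lib.stride_tricks.sliding_window_view(onehot, P, axis=0)  # (L, 4, P)
    return np.ascontiguousarray(win.reshape(4 * L, P))


def _onehot_reads(codes: np.ndarray) -> np.ndarray:
    """(n, L) base codes -> (n, 4*L) float32 one-hot (N rows all-zero)."""
    n, L = codes.shape
    oh = np.zeros((n, L, 4), dtype=np.float32)
    idx = np.nonzero(codes < 4)
    oh[idx[0], idx[1], codes[idx]] = 1.0
    return oh.reshape(n, 4 * L)


def _best_placements(
    reads_oh: np.ndarray, read_len: int, ref: SequenceRecord
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best score, offset and strand per read against one reference.

    Ties between strands prefer '+'; ties between offsets take the leftmost
    (argmax convention), fixing determinism.
    """
    n = reads_oh.shape[0]
    fwd = _encode(ref.residues)
    scores = np.zeros(n, dtype=np.float32)
    offsets = np.zeros(n, dtype=np.int64)
    strands = np.zeros(n, dtype=np.int8)  # 0 = '+', 1 = '-'
    Yf = _window_matrix(fwd, read_len)
    if Yf is None:
        return scores, offsets, strands
    Mf = reads_oh @ Yf
    sf = Mf.max(axis=1)
    of = Mf.argmax(axis=1)
    rc = _encode(revcomp(ref.residues))
    Mr = reads_oh @ _window_matrix(rc, read_len)
    sr = Mr.max(axis=1)
    orr = Mr.argmax(axis=1)
    minus = sr > sf
    scores = np.where(minus, sr, sf)
    offsets = np.where(minus, orr, of)
    strands = minus.astype(np.int8)
    return scores, offsets, strands


def map_reads(
    reads: Sequence[ReadRecord],
    refs: Sequence[SequenceRecord],
    min_score: int,
    batch: int = 2048,
) -> List[List[AlignmentHit]]:
    """Map a batch of reads against references; one hit list per read.

    For each reference a read gets at most one hit — the reference's own best
    placement over both strands — and only if its score reaches ``min_score``.
    Equivalent to exhaustively scoring every ungapped placement.
    """
    out: List[List[AlignmentHit]] = [[] for _ in reads]
    if not reads or not refs:
        return out
    by_len: Dict[int, List[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r), []).append(i)
    for L, idxs in by_len.items():
        if L == 0:
            continue
        for lo in range(0, len(idxs), batch):
            chunk = idxs[lo : lo + batch]
            codes = np.stack([_encode(reads[i].bases) for i in chunk])
            oh = _onehot_reads(codes)
            for ref in refs:
                if len(ref) < L:
                    continue
                scores, offsets, strands = _best_placements(oh, L, ref)
                R = len(ref)
                for j, i in enumerate(chunk):
                    sc = int(round(float(scores[j])))
                    if sc < min_score:
                        continue
                    o = int(offsets[j])
                    if strands[j] == 0:
                        s_start, s_end, strand = o + 1, o + L, "+"
                    else:
                        # offset o on the reverse complement maps back to
                        # forward window [R-L-o, R-o-1] traversed 3'->5'
                        s_start, s_end, strand = R - o, R - o - L + 1, "-"
                    out[i].append(
                        AlignmentHit(
                            query_id=reads[i].read_id,
                            subject=ref.accession,
                            identity=100.0 * sc / L,
                            aligned_length=L,
                            score=float(sc),
                            evalue=0.0,
                            q_start=1,
                            q_end=L,
                            s_start=s_start,
                            s_end=s_end,
                            strand=strand,
                        )
                    )
    return out


def kmer_map(
    read: ReadRecord, refs: Sequence[SequenceRecord], min_score: int
) -> List[AlignmentHit]:
    """Map one read against references (see :func:`map_reads`)."""
    return map_reads([read], refs, min_score)[0]


def map_sequence(
    query_id: str, residues: str, refs: Sequence[SequenceRecord], min_score: int
) -> List[AlignmentHit]:
    """Map an arbitrary query sequence (e.g. an assembled contig).

    When the query is longer than a reference the roles are swapped for the
    placement scan (the shorter sequence slides within the longer); the hit
    still reports query/subject in the caller's orientation.
    """
    hits: List[AlignmentHit] = []
    q = ReadRecord(read_id=query_id, mate=1, bases=residues, quals=[0] * len(residues))
    shorter_refs = [r for r in refs if len(r) >= len(residues)]
    hits.extend(map_reads([q], shorter_refs, min_score)[0])
    for ref in refs:
        if len(ref) >= len(residues):
            continue
        pseudo = ReadRecord(
            read_id=ref.accession, mate=1, bases=ref.residues, quals=[0] * len(ref)
        )
        target = SequenceRecord(accession=query_id, description="", residues=residues)
        for h in map_reads([pseudo], [target], min_score)[0]:
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject=ref.accession,
                    identity=h.identity,
                    aligned_length=h.aligned_length,
                    score=h.score,
                    evalue=0.0,
                    q_start=min(h.s_start, h.s_end),
                    q_end=max(h.s_start, h.s_end),
                    s_start=h.q_start if h.strand == "+" else h.q_end,
                    s_end=h.q_end if h.strand == "+" else h.q_start,
                    strand=h.strand,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# abundance table and taxonomy rollups
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Samples x references matrix of summed fractional weights.

    ``values`` is a DataFrame indexed by reference accession (or, after
    :func:`rollup`, by rank label) with one column per sample. ``lineage``
    and ``groups`` ride along for reporting.
    """

    values: pd.DataFrame
    lineage: Optional[LineageTable] = None
    groups: Dict[str, str] = field(default_factory=dict)
    rank: Optional[str] = None  # None = reference level

    @property
    def references(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)


def abundance_table(
    per_sample_assignments: Mapping[str, Sequence[ReadAssignment]],
    lineage: Optional[LineageTable] = None,
    groups: Optional[Mapping[str, str]] = None,
    references: Optional[Sequence[str]] = None,
) -> AbundanceTable:
    """Sum fractional weights into the samples x references table.

    Accumulation uses exact rational arithmetic (each read contributes 1/m to
    m references), so a sample's column sum equals its assigned-read count to
    within one rounding of each cell — the conservation law the whole
    quantification rests on.
    """
    ref_set: Dict[str, None] = {}
    if references is not None:
        for acc in references:
            ref_set[acc] = None
    cells: Dict[str, Dict[str, Fraction]] = {}
    for sample, assignments in per_sample_assignments.items():
        col = cells.setdefault(sample, {})
        for a in assignments:
            m = len(a.weights)
            if m == 0:
                continue
            w = Fraction(1, m)
            for acc, _ in a.weights:
                col[acc] = col.get(acc, Fraction(0)) + w
                ref_set.setdefault(acc, None)
    index = sorted(ref_set) if references is None else list(ref_set)
    samples = list(per_sample_assignments)
    data = np.zeros((len(index), len(samples)))
    pos = {acc: i for i, acc in enumerate(index)}
    for j, sample in enumerate(samples):
        for acc, val in cells.get(sample, {}).items():
            data[pos[acc], j] = float(val)
    df = pd.DataFrame(data, index=pd.Index(index, name="accession"), columns=samples)
    return AbundanceTable(values=df, lineage=lineage, groups=dict(groups or {}))


def rollup(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Aggregate reference rows by a taxonomy rank; per-sample totals are
    conserved. References absent from the lineage land in the ``unknown``
    sentinel row."""
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomy rank {rank!r}; expected one of {RANKS}")
    lineage = table.lineage if table.lineage is not None else LineageTable()
    labels = [lineage.label(acc, rank) for acc in table.values.index]
    rolled = table.values.groupby(pd.Index(labels, name=rank), sort=True).sum()
    return AbundanceTable(
        values=rolled, lineage=table.lineage, groups=table.groups, rank=rank
    )


# ---------------------------------------------------------------------------
# external remap ingestion (minimal SAM subset)
# ---------------------------------------------------------------------------


def assignments_from_sam(hits_by_read: Mapping[str, Sequence[AlignmentHit]],
                         tie_tolerance: float = 0.0) -> List[ReadAssignment]:
    """Turn externally produced per-read hits (e.g. parsed from SAM) into
    assignments: tied references are all records for a read sharing the
    maximal alignment score; reads with no hits are unassigned."""
    return [
        assign_read(list(hits), tie_tolerance=tie_tolerance)
        if hits
        else ReadAssignment(read_id=rid, weights=[])
        for rid, hits in hits_by_read.items()
    ]
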