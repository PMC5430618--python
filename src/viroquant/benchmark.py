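"""Rank-level benchmark evaluation of read assignments against truth labels.

Given per-read fractional assignments and a truth table from the simulator
(or any labelled dataset), computes per-rank assignment metrics: how many of
the reads assignable at a rank received a resolving call (assigned %), how
many calls were right (correct % / precision), recall against all assignable
reads, and the F-measure. Metrics are computed from raw counts
(micro-averaged), not from pre-rounded percentages.

A read's call at a rank is its weight-majority label: fractional weights are
summed per rank label through the lineage, and the unique maximal label wins.
An exact tie between *different* labels is an ambiguous call — assigned but
incorrect at that rank — while references tied within the same higher-rank
taxon merge into one label and stay correct, preserving the point of score
splitting: ambiguity below species need not cost accuracy at genus or family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .records import RANKS, UNKNOWN, Lineage, LineageTable
from .quantify import ReadAssignment

CLASSES = ("human", "bacterial", "viral")


@dataclass(slots=True)
class TruthRow:
    read_id: str
    cls: str  # human | bacterial | viral
    lineage: Lineage = Lineage()
    origin: str = UNKNOWN  # source accession (e.g. rRNA vs genomic)


@dataclass
class TruthTable:
    rows: Dict[str, TruthRow] = field(default_factory=dict)

    def add(self, row: TruthRow) -> None:
        if row.read_id in self.rows:
            raise ValueError(f"duplicate truth row for read {row.read_id}")
        self.rows[row.read_id] = row

    def lookup(self, read_id: str) -> Optional[TruthRow]:
        """Truth for a read; mate suffixes (/1, /2) fall back to the pair."""
        row = self.rows.get(read_id)
        if row is None and read_id[-2:] in ("/1", "/2"):
            row = self.rows.get(read_id[:-2])
        return row

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(slots=True)
class BenchmarkReport:
    rank: str
    assignable: int
    assigned: int
    correct: int
    assigned_pct: float
    correct_pct: float
    precision: float
    recall: float
    f_measure: float
    unclassified_pct: float
    degenerate: bool = False  # flags 0-assigned runs where precision is undefined


def _normalize(read_id: str) -> str:
    """Strip a /1 or /2 mate suffix so mates aggregate onto their pair."""
    return read_id[:-2] if read_id[-2:] in ("/1", "/2") else read_id


def _majority_label(
    weights: Sequence[Tuple[str, float]], lineage: LineageTable, rank: str
) -> Optional[str]:
    """Weight-majority rank label, or None when no label resolves the rank
    (unknown sentinel or an exact tie between different labels)."""
    totals: Dict[str, float] = {}
    for acc, w in weights:
        label = lineage.label(acc, rank)
        totals[label] = totals.get(label, 0.0) + w
    totals.pop(UNKNOWN, None)
    if not totals:
        return None
    best = max(totals.values())
    winners = [label for label, w in totals.items() if w >= best - 1e-12]
    if len(winners) == 1:
        return winners[0]
    return "__ambiguous__"


def evaluate(
    assignments: Sequence[ReadAssignment],
    truth: TruthTable,
    rank: str,
    lineage: LineageTable,
) -> BenchmarkReport:
    """Per-rank metrics for viral reads.

    Mates sharing a truth row (ids differing only in a /1 or /2 suffix) are
    merged: their fractional weights are summed before the majority call, so
    each truth row is evaluated once. Assignable reads are those whose truth
    class is viral with a defined label at the rank. assigned% =
    assigned/assignable; correct% = precision = correct/assigned; recall =
    correct/assignable; F = 2PR/(P+R); unclassified% = share of assignable
    reads without a resolving call.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomy rank {rank!r}; expected one of {RANKS}")
    by_read: Dict[str, Dict[str, float]] = {}
    for a in assignments:
        combined = by_read.setdefault(_normalize(a.read_id), {})
        for acc, w in a.weights:
            combined[acc] = combined.get(acc, 0.0) + w
    assignable = assigned = correct = 0
    for read_id, row in truth.rows.items():
        if row.cls != "viral":
            continue
        true_label = getattr(row.lineage, rank)
        if true_label == UNKNOWN:
            continue
        assignable += 1
        combined = by_read.get(read_id)
        if not combined:
            continue
        call = _majority_label(list(combined.items()), lineage, rank)
        if call is None:
            continue
        assigned += 1
        if call == true_label:
            correct += 1
    degenerate = assigned == 0
    precision = 0.0 if degenerate else 100.0 * correct / assigned
    recall = 0.0 if assignable == 0 else 100.0 * correct / assignable
    assigned_pct = 0.0 if assignable == 0 else 100.0 * assigned / assignable
    f = 0.0
    if precision > 0 and recall > 0:
        f = 2 * precision * recall / (precision + recall)
    return BenchmarkReport(
        rank=rank,
        assignable=assignable,
        assigned=assigned,
        correct=correct,
        assigned_pct=assigned_pct,
        correct_pct=precision,
        precision=precision,
        recall=recall,
        f_measure=f,
        unclassified_pct=100.0 - assigned_pct if assignable else 0.0,
        degenerate=degenerate,
    )


def composition_summary(truth: TruthTable) -> Dict[str, float]:
    """Percent of reads per class (human/bacterial/viral), 1-decimal."""
    if len(truth) == 0:
        raise ValueError("empty truth table")
    counts = {cls: 0 for cls in CLASSES}
    for row in truth.rows.values():
        counts[row.cls] = counts.get(row.cls, 0) + 1
    total = sum(counts.values())
    return {cls: round(100.0 * n / total, 1) for cls, n in counts.items()}


def composition_from_counts(counts: Mapping[str, int]) -> Dict[str, float]:
    """Class percentages straight from printed per-class read counts."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty counts")
    return {cls: round(100.0 * n / total, 1) for cls, n in counts.items()}
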