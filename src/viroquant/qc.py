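"""Quality trimming, pair interlacing and the assembly-input subsampling
policy.

Trimming is a 3' sliding-window rule (width 4, mean Phred quality): the 3'
end is shrunk while the trailing window mean sits below the threshold, then
any remaining trailing bases individually below the threshold are stripped.
This two-phase rule is idempotent and removes exactly the low-quality tail of
a read whose 3' end degrades. Reads shorter than ``min_length`` after
trimming, or with more than 10% N among remaining bases, are rejected.

Subsampling applies only to assembly input (defaults: 75% of reads, capped at
1,000,000 per sample); the full QC-passed read set is retained for remapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, TypeVar

import numpy as np

from .records import ReadRecord

DEFAULT_QUALITY_THRESHOLD = 20
DEFAULT_MIN_LENGTH = 50
DEFAULT_MAX_N_FRACTION = 0.10
TRIM_WINDOW = 4

DEFAULT_SUBSAMPLE_FRACTION = 0.75
DEFAULT_SUBSAMPLE_CAP = 1_000_000

T = TypeVar("T")


@dataclass(slots=True)
class QCReport:
    """Per-sample read accounting through QC, interlacing and subsampling."""

    sample_id: str
    reads_in: int = 0
    reads_after_trim: int = 0
    pairs_interlaced: int = 0
    orphans: int = 0
    reads_subsampled: int = 0

    def validate(self) -> None:
        if not (self.reads_in >= self.reads_after_trim >= self.reads_subsampled >= 0):
            raise ValueError(
                f"QC counts not monotone for {self.sample_id}: "
                f"{self.reads_in} >= {self.reads_after_trim} >= "
                f"{self.reads_subsampled} violated"
            )


def trim_read(
    read: ReadRecord,
    quality_threshold: int = DEFAULT_QUALITY_THRESHOLD,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> Optional[ReadRecord]:
    """Trim the 3' low-quality tail; return the trimmed read or None.

    Rejection (None) is a value, not an error: it feeds the orphan/paired
    bookkeeping in :func:`interlace`.
    """
    if quality_threshold < 0 or min_length < 0:
        raise ValueError("thresholds must be non-negative")
    quals = read.quals
    end = len(quals)
    # Alternate the two phases to a fixpoint: the result then has a trailing
    # window mean >= threshold AND a final base >= threshold, which is exactly
    # what each phase checks first — so trimming is idempotent.
    while True:
        start_end = end
        # phase 1: shrink while the trailing width-4 window mean is low
        while end > 0:
            window = quals[max(0, end - TRIM_WINDOW) : end]
            if sum(window) / len(window) >= quality_threshold:
                break
            end -= 1
        # phase 2: strip trailing bases individually below threshold
        while end > 0 and quals[end - 1] < quality_threshold:
            end -= 1
        if end == start_end or end == 0:
            break
    if end < min_length or end == 0:
        return None
    bases = read.bases[:end]
    if bases.upper().count("N") > max_n_fraction * end:
        return None
    if end == len(read.bases):
        return read
    return ReadRecord(read.read_id, read.mate, bases, quals[:end])


def interlace(
    r1: Sequence[ReadRecord], r2: Sequence[ReadRecord]
) -> Tuple[List[ReadRecord], List[ReadRecord]]:
    """Merge surviving mates into one alternating stream.

    ``r1``/``r2`` are the post-trim survivors of each mate file, in original
    file order. Pairs with both mates present are emitted R1-then-R2; reads
    whose mate was rejected become orphans (returned separately, still usable
    for assembly and remapping).
    """
    for stream, name in ((r1, "R1"), (r2, "R2")):
        seen = set()
        for rec in stream:
            if rec.read_id in seen:
                raise ValueError(f"duplicate read id in {name}: {rec.read_id}")
            seen.add(rec.read_id)
    by_id_2: Dict[str, ReadRecord] = {rec.read_id: rec for rec in r2}
    interleaved: List[ReadRecord] = []
    orphans: List[ReadRecord] = []
    matched = set()
    for rec in r1:
        mate = by_id_2.get(rec.read_id)
        if mate is None:
            orphans.append(rec)
        else:
            interleaved.extend((rec, mate))
            matched.add(rec.read_id)
    orphans.extend(rec for rec in r2 if rec.read_id not in matched)
    return interleaved, orphans


def _round_half_away(x: float) -> int:
    """Round half away from zero (cross-language determinism; Python's
    built-in round is banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def subsample(
    reads: Sequence[T],
    fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    cap: int = DEFAULT_SUBSAMPLE_CAP,
    seed: int = 0,
) -> List[T]:
    """Uniform random sample without replacement, original order preserved.

    Sample size is min(round(fraction * n), cap) with round-half-away-from-
    zero. Deterministic for a given seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n = len(reads)
    size = min(_round_half_away(fraction * n), cap)
    if size >= n:
        return list(reads)
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = rng.choice(n, size=size, replace=False)
    idx.sort()
    return [reads[i] for i in idx]
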