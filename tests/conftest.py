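"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (full DP
alignment, exhaustive placement scans) kept independent of the library code
paths they check.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pytest

from viroquant import simdata
from viroquant.records import ReadRecord, SequenceRecord, revcomp


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def dp_max_matches(a: str, b: str) -> int:
    """Needleman-Wunsch with match=+1, mismatch/gap=0: the maximum number of
    identical aligned positions over all global alignments."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = max(
                prev[j - 1] + (1 if ai == b[j - 1] else 0),
                prev[j],
                cur[j - 1],
            )
        prev = cur
    return prev[m]


def oracle_identity(a: str, b: str) -> float:
    return dp_max_matches(a, b) / min(len(a), len(b))


def oracle_best_placement(read: str, ref: str) -> Tuple[int, int, str]:
    """Exhaustive all-placements, both-strands scan.

    Returns (score, offset, strand) of the best ungapped placement of the
    read within the reference; '+' preferred on strand ties, leftmost offset
    on offset ties. Score = count of matching bases (N never matches).
    """
    L = len(read)
    best = (0, 0, "+")
    for strand, oriented in (("+", read), ("-", None)):
        query = oriented if oriented is not None else revcomp(read)
        for offset in range(len(ref) - L + 1):
            window = ref[offset : offset + L]
            if strand == "+":
                score = sum(
                    1 for x, y in zip(query, window) if x == y and x in "ACGT"
                )
                if score > best[0]:
                    best = (score, offset, "+")
            else:
                # minus strand: align revcomp(read) to the forward window
                score = sum(
                    1 for x, y in zip(query, window) if x == y and x in "ACGT"
                )
                if score > best[0]:
                    best = (score, offset, "-")
    return best


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_read(read_id: str, bases: str, qual: int = 30, mate: int = 1) -> ReadRecord:
    return ReadRecord(read_id=read_id, mate=mate, bases=bases, quals=[qual] * len(bases))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def reference_set() -> simdata.ReferenceSet:
    """One labelled synthetic reference set reused across tests."""
    return simdata.make_references(seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(202401))
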