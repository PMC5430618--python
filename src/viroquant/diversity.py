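"""Alpha diversity, population profiles and heatmap orderings.

Shannon entropy H = -sum(p_i ln p_i) in nats is the within-sample (alpha)
diversity of a taxon-abundance distribution; richness is the number of taxa
with positive weight. Population profiles aggregate sample columns into
user-defined groups and normalise to proportions at a chosen taxonomy rank;
regrouping reuses the same abundance table, so group assignments can be
changed without re-quantifying. Heatmap orderings come from average-linkage
hierarchical clustering of log10(x+1)-transformed values with Euclidean
distance — a conventional, reproducible choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .quantify import AbundanceTable, rollup

DEFAULT_RANK = "species"
UNGROUPED = "ungrouped"


@dataclass(slots=True)
class DiversityRow:
    sample_id: str
    shannon: float
    richness: int


def shannon(abundances: Sequence[float]) -> float:
    """Shannon entropy (nats) of an abundance vector.

    Zeros are ignored (0 ln 0 = 0); the vector must have positive sum.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute entropy of an all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum()) + 0.0  # +0.0 normalises -0.0


def diversity_report(
    table: AbundanceTable, rank: str = DEFAULT_RANK
) -> List[DiversityRow]:
    """Per-sample Shannon entropy and richness at a taxonomy rank."""
    rolled = rollup(table, rank) if table.rank != rank else table
    rows = []
    for sample in rolled.values.columns:
        col = rolled.values[sample].to_numpy()
        richness = int((col > 0).sum())
        h = shannon(col) if richness >= 1 else 0.0
        rows.append(DiversityRow(sample_id=sample, shannon=h, richness=richness))
    return rows


def population_profile(
    table: AbundanceTable,
    rank: str,
    grouping: Optional[Mapping[str, str]] = None,
) -> Dict[str, Dict[str, object]]:
    """Per-group rank-level proportion vectors.

    Each group's vector is the column sum of its member samples, rolled up to
    ``rank`` and normalised; ``total`` records the group's summed weight (pie
    size is proportional to total hits). Samples missing from the grouping
    fall into "ungrouped".
    """
    grouping = dict(grouping or {})
    rolled = rollup(table, rank)
    groups: Dict[str, List[str]] = {}
    for sample in rolled.values.columns:
        groups.setdefault(grouping.get(sample, UNGROUPED), []).append(sample)
    out: Dict[str, Dict[str, object]] = {}
    for group in sorted(groups):
        vec = rolled.values[groups[group]].sum(axis=1)
        total = float(vec.sum())
        props = (vec / total) if total > 0 else vec
        out[group] = {
            "total": total,
            "proportions": {
                label: float(v) for label, v in props.items() if v > 0
            },
        }
    return out


def regroup(
    table: AbundanceTable, rank: str, new_grouping: Mapping[str, str]
) -> Dict[str, Dict[str, object]]:
    """Recompute profiles under a new sample->group mapping.

    Works from the same abundance table — no re-quantification — and never
    touches the table's values.
    """
    unknown = sorted(set(new_grouping) - set(table.values.columns))
    if unknown:
        raise ValueError(f"grouping references unknown samples: {', '.join(unknown)}")
    return population_profile(table, rank, new_grouping)


def heatmap_order(
    table: AbundanceTable,
) -> Tuple[List[str], List[str], Optional[np.ndarray], Optional[np.ndarray]]:
    """Leaf orders and linkage trees for a clustered heatmap.

    Returns (sample order, taxon order, sample linkage, taxon linkage).
    Values are log10(x+1)-transformed; distances are Euclidean; linkage is
    average (UPGMA). With fewer than two rows or columns the identity
    ordering is returned with a None tree.
    """
    values = np.log10(table.values.to_numpy(dtype=float) + 1.0)
    taxa = list(table.values.index)
    samples = list(table.values.columns)
    taxon_link = sample_link = None
    taxon_order, sample_order = taxa, samples
    if len(taxa) >= 2:
        taxon_link = linkage(pdist(values, metric="euclidean"), method="average")
        taxon_order = [taxa[i] for i in leaves_list(taxon_link)]
    if len(samples) >= 2:
        sample_link = linkage(pdist(values.T, metric="euclidean"), method="average")
        sample_order = [samples[i] for i in leaves_list(sample_link)]
    return sample_order, taxon_order, sample_link, taxon_link
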