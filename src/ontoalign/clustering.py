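"""Agglomerative extraction of equivalent concept pairs.

Every concept starts as a singleton cluster.  The most similar admissible
cluster pair — one singleton from each ontology, neither merged before —
is merged repeatedly until the best remaining inter-ontology similarity
drops below the threshold.  Because the output is a set of *equivalent
pairs*, clusters are capped at size two with one member per ontology, so
the procedure reduces to greedy maximum-first bipartite matching with a
similarity floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["Alignment", "AlignedPair", "cluster_alignment"]


@dataclass(frozen=True)
class AlignedPair:
    source: str
    target: str
    similarity: float


@dataclass
class Alignment:
    """Equivalent concept pairs with their overall similarities.

    Pairs form a partial matching (no concept appears twice), each pair's
    similarity is at least the threshold, and the list is sorted by
    descending similarity with (source, target) id tie-break.
    """

    pairs: List[AlignedPair] = field(default_factory=list)
    threshold: float = 0.0

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def as_tuples(self) -> List[Tuple[str, str]]:
        return [(p.source, p.target) for p in self.pairs]


def cluster_alignment(matrix: SimilarityMatrix, threshold: float) -> Alignment:
    """Merge singleton clusters greedily down to the similarity threshold.

    Ties on similarity are broken lexicographically on (source id,
    target id) for determinism.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    grid = matrix.overall
    candidates = []
    for i, source in enumerate(matrix.row_ids):
        for j, target in enumerate(matrix.col_ids):
            sim = float(grid[i, j])
            if sim >= threshold:
                candidates.append((-sim, source, target))
    candidates.sort()
    used_rows: set[str] = set()
    used_cols: set[str] = set()
    pairs: List[AlignedPair] = []
    for neg_sim, source, target in candidates:
        if source in used_rows or target in used_cols:
            continue
        used_rows.add(source)
        used_cols.add(target)
        pairs.append(AlignedPair(source, target, -neg_sim))
    return Alignment(pairs=pairs, threshold=threshold)
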