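"""Four-aspect semantic similarity between concepts of two ontologies.

For a concept pair the aspects are:

* **S1** — label similarity (exact/synonym match or edit-distance based);
* **S2** — fraction of properties matched one-to-one between the two
  property lists (Dice form ``2m / (|Pa| + |Pb|)``);
* **S3** — similarity of the ``is_a`` ancestor lists, averaged over the
  longer list so depth mismatch dilutes the score;
* **S4** — fraction of matched ``hasBinding`` relationship targets, the
  miR-domain relationship linking a microRNA concept to its mRNA
  binding-site concepts (Dice form again).

One-to-one matching follows the stable-marriage principle: candidate pairs
are taken greedily in descending similarity, and once an element is matched
it never participates again.  The overall similarity is the weighted sum of
the four aspects under a weight vector on the probability simplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .lexical import SynonymLexicon, name_similarity
from .model import ConceptGraph, ancestors

__all__ = [
    "SimilarityVector",
    "WeightVector",
    "SimilarityMatrix",
    "UNIFORM_WEIGHTS",
    "DEFAULT_THETA_MATCH",
    "greedy_match",
    "property_similarity",
    "isa_similarity",
    "binding_similarity",
    "similarity_vector",
    "overall_similarity",
    "build_matrix",
]

#: Default floor a candidate pair must reach to count as matched in the
#: property and binding aspects.
DEFAULT_THETA_MATCH = 0.9

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityVector:
    """Per-pair aspect similarities, each in [0, 1]."""

    s1_name: float
    s2_properties: float
    s3_isa: float
    s4_binding: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.s1_name, self.s2_properties, self.s3_isa, self.s4_binding]
        )


@dataclass(frozen=True)
class WeightVector:
    """Aspect weights w1..w4: nonnegative, summing to 1."""

    w1: float
    w2: float
    w3: float
    w4: float

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < 0):
            raise ValueError(f"weights must be nonnegative, got {arr}")
        if abs(arr.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"weights must sum to 1, got sum {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "WeightVector":
        w1, w2, w3, w4 = (float(x) for x in arr)
        return cls(w1, w2, w3, w4)


UNIFORM_WEIGHTS = WeightVector(0.25, 0.25, 0.25, 0.25)


def greedy_match(
    names_a: Sequence[str],
    names_b: Sequence[str],
    lexicon: SynonymLexicon | None = None,
    floor: float = 0.0,
) -> List[Tuple[int, int, float]]:
    """One-to-one matching of two name lists by descending similarity.

    Implements the stable-marriage principle used throughout the aspect
    measures: pairs are considered from the most similar down (ties broken
    lexicographically on the name pair, then on indices for duplicate
    names); once either side is matched it is removed from consideration.
    Pairs scoring below ``floor`` are never matched.

    Returns the matched (index_a, index_b, similarity) triples.
    """
    candidates = []
    for i, a in enumerate(names_a):
        for j, b in enumerate(names_b):
            sim = name_similarity(a, b, lexicon)
            if sim >= floor:
                candidates.append((-sim, a, b, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: List[Tuple[int, int, float]] = []
    for neg_sim, _a, _b, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j, -neg_sim))
    return matched


def property_similarity(
    props_a: Sequence[str],
    props_b: Sequence[str],
    lexicon: SynonymLexicon | None = None,
    theta_match: float = DEFAULT_THETA_MATCH,
) -> float:
    """Fraction of properties matched one-to-one: ``2m / (|Pa| + |Pb|)``.

    A candidate pair counts as matched only when its name similarity
    reaches ``theta_match``.  Two empty property lists score 0 — absence of
    properties carries no evidence of equivalence.
    """
    if not props_a and not props_b:
        return 0.0
    m = len(greedy_match(props_a, props_b, lexicon, floor=theta_match))
    return 2.0 * m / (len(props_a) + len(props_b))


def isa_similarity(
    g1: ConceptGraph,
    g2: ConceptGraph,
    a: str,
    b: str,
    lexicon: SynonymLexicon | None = None,
) -> float:
    """Similarity of the two ``is_a`` ancestor lists.

    Ancestor names are matched one-to-one by descending name similarity;
    the matched similarities are summed and averaged over the longer list,
    so unmatched ancestors dilute the score.  Two root concepts (both lists
    empty) score 1; a root against a non-root scores 0.
    """
    anc_a = [g1[c].name for c in ancestors(g1, a)]
    anc_b = [g2[c].name for c in ancestors(g2, b)]
    if not anc_a and not anc_b:
        return 1.0
    if not anc_a or not anc_b:
        return 0.0
    matched = greedy_match(anc_a, anc_b, lexicon)
    return sum(sim for _i, _j, sim in matched) / max(len(anc_a), len(anc_b))


def binding_similarity(
    g1: ConceptGraph,
    g2: ConceptGraph,
    a: str,
    b: str,
    lexicon: SynonymLexicon | None = None,
    theta_match: float = DEFAULT_THETA_MATCH,
) -> float:
    """Fraction of matched ``hasBinding`` targets: ``2m / (|Ba| + |Bb|)``.

    Targets are compared by concept name under the same one-to-one greedy
    matching and ``theta_match`` floor as the property aspect.  Concepts on
    both sides without binding targets score 0.
    """
    targets_a = [g1[t].name for t in g1[a].relations.get("hasBinding", [])]
    targets_b = [g2[t].name for t in g2[b].relations.get("hasBinding", [])]
    if not targets_a and not targets_b:
        return 0.0
    m = len(greedy_match(targets_a, targets_b, lexicon, floor=theta_match))
    return 2.0 * m / (len(targets_a) + len(targets_b))


def similarity_vector(
    g1: ConceptGraph,
    g2: ConceptGraph,
    a: str,
    b: str,
    lexicon: SynonymLexicon | None = None,
    theta_match: float = DEFAULT_THETA_MATCH,
) -> SimilarityVector:
    """All four aspect similarities for the concept pair (a, b)."""
    ca, cb = g1[a], g2[b]
    return SimilarityVector(
        s1_name=name_similarity(ca.name, cb.name, lexicon),
        s2_properties=property_similarity(
            ca.properties, cb.properties, lexicon, theta_match
        ),
        s3_isa=isa_similarity(g1, g2, a, b, lexicon),
        s4_binding=binding_similarity(g1, g2, a, b, lexicon, theta_match),
    )


def overall_similarity(v: SimilarityVector, w: WeightVector) -> float:
    """Weighted sum of the four aspects; in [0, 1] by convexity."""
    return float(v.as_array() @ w.as_array())


class SimilarityMatrix:
    """All-pairs similarity between two ontologies' concepts.

    The per-pair aspect components are computed once and cached as an
    ``n_rows x n_cols x 4`` array; the overall grid is the dot product of
    the components with the current weight vector and can be recomputed
    cheaply after a weight change.
    """

    def __init__(
        self,
        row_ids: Sequence[str],
        col_ids: Sequence[str],
        components: np.ndarray,
        weights: WeightVector,
    ):
        components = np.asarray(components, dtype=float)
        if components.shape != (len(row_ids), len(col_ids), 4):
            raise ValueError(
                f"components shape {components.shape} does not match "
                f"{len(row_ids)} rows x {len(col_ids)} cols x 4 aspects"
            )
        self.row_ids = list(row_ids)
        self.col_ids = list(col_ids)
        self.components = components
        self._row_index = {cid: i for i, cid in enumerate(self.row_ids)}
        self._col_index = {cid: j for j, cid in enumerate(self.col_ids)}
        self.weights = weights
        self.overall = components @ weights.as_array()

    def reweight(self, weights: WeightVector) -> None:
        """Recompute the overall grid under new weights (components cached)."""
        self.weights = weights
        self.overall = self.components @ weights.as_array()

    def cell(self, source_id: str, target_id: str) -> Tuple[int, int]:
        try:
            return self._row_index[source_id], self._col_index[target_id]
        except KeyError as exc:
            raise KeyError(
                f"concept pair ({source_id!r}, {target_id!r}) not in matrix"
            ) from exc


def build_matrix(
    g1: ConceptGraph,
    g2: ConceptGraph,
    weights: WeightVector = UNIFORM_WEIGHTS,
    lexicon: SynonymLexicon | None = None,
    theta_match: float = DEFAULT_THETA_MATCH,
) -> SimilarityMatrix:
    """Compute the all-pairs similarity matrix between two graphs.

    Rows follow ``g1``, columns follow ``g2``, both in sorted-id order.
    """
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("cannot build a similarity matrix over an empty graph")
    row_ids = g1.ids()
    col_ids = g2.ids()
    components = np.empty((len(row_ids), len(col_ids), 4))
    for i, a in enumerate(row_ids):
        for j, b in enumerate(col_ids):
            components[i, j, :] = similarity_vector(
                g1, g2, a, b, lexicon, theta_match
            ).as_array()
    return SimilarityMatrix(row_ids, col_ids, components, weights)
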