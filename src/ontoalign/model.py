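"""In-memory concept-graph model shared by ontologies and database schemas.

An ontology (or a relational schema mapped onto the same vocabulary) is a
collection of named concepts carrying property lists, ``is_a`` parent links
forming a rooted directed acyclic graph, and typed relationships such as
``hasBinding`` pointing at other concepts.  Instance-level data is carried
through untouched: all similarity computation happens at the schema level.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import networkx as nx

__all__ = [
    "Concept",
    "ConceptGraph",
    "DagError",
    "UnknownConceptError",
    "ancestors",
    "assert_dag",
]


class UnknownConceptError(KeyError):
    """Raised when a concept id does not resolve within its graph."""


class DagError(ValueError):
    """Raised when the ``is_a`` edge set contains a directed cycle."""

    def __init__(self, cycle: List[str]):
        self.cycle = cycle
        super().__init__(f"is_a cycle detected: {' -> '.join(cycle + cycle[:1])}")


@dataclass
class Concept:
    """A single ontology term / schema table.

    Parameters
    ----------
    id:
        Namespaced identifier, unique within its graph (e.g. ``GO:0001234``).
    name:
        Primary human-readable label.
    synonyms:
        Alternate labels; used only as extra lexical handles.
    definition:
        Optional free-text definition.
    properties:
        Property (attribute) names attached to the concept.
    parents:
        ``is_a`` parent concept ids.
    relations:
        Typed relationships, relationship name -> list of target concept ids
        (e.g. ``{"hasBinding": ["T:17"]}``).
    instances:
        Opaque instance labels, carried through but never used in matching.
    annotations:
        Unrecognised source-file tags, preserved verbatim as (tag, value).
    """

    id: str
    name: str
    synonyms: List[str] = field(default_factory=list)
    definition: Optional[str] = None
    properties: List[str] = field(default_factory=list)
    parents: List[str] = field(default_factory=list)
    relations: Dict[str, List[str]] = field(default_factory=dict)
    instances: List[str] = field(default_factory=list)
    annotations: List[Tuple[str, str]] = field(default_factory=list)

    def copy(self) -> "Concept":
        return Concept(
            id=self.id,
            name=self.name,
            synonyms=list(self.synonyms),
            definition=self.definition,
            properties=list(self.properties),
            parents=list(self.parents),
            relations={k: list(v) for k, v in self.relations.items()},
            instances=list(self.instances),
            annotations=list(self.annotations),
        )


class ConceptGraph:
    """A named set of concepts with resolution and DAG utilities."""

    def __init__(self, name: str = "", concepts: Iterable[Concept] = ()):
        self.name = name
        self._concepts: Dict[str, Concept] = {}
        self.relationship_catalogue: set[str] = set()
        self.property_catalogue: set[str] = set()
        for c in concepts:
            self.add(c)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self):
        return iter(self._concepts.values())

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __getitem__(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(
                f"concept {concept_id!r} not found in graph {self.name!r}"
            ) from None

    @property
    def concepts(self) -> Mapping[str, Concept]:
        return self._concepts

    def ids(self) -> List[str]:
        """All concept ids in sorted order."""
        return sorted(self._concepts)

    def add(self, concept: Concept) -> None:
        if not concept.id:
            raise ValueError("concept id must be nonempty")
        if concept.id in self._concepts:
            raise ValueError(f"duplicate concept id {concept.id!r}")
        if concept.id in concept.parents:
            raise ValueError(f"concept {concept.id!r} is its own parent")
        self._concepts[concept.id] = concept
        self.property_catalogue.update(concept.properties)
        self.relationship_catalogue.update(concept.relations)

    def validate(self) -> None:
        """Check referential integrity and acyclicity; raise on violation."""
        for c in self:
            for p in c.parents:
                if p not in self._concepts:
                    raise UnknownConceptError(
                        f"concept {c.id!r}: is_a target {p!r} does not resolve"
                    )
            for rel, targets in c.relations.items():
                for t in targets:
                    if t not in self._concepts:
                        raise UnknownConceptError(
                            f"concept {c.id!r}: {rel} target {t!r} does not resolve"
                        )
        assert_dag(self)

    def copy(self) -> "ConceptGraph":
        g = ConceptGraph(self.name, (c.copy() for c in self))
        g.relationship_catalogue |= self.relationship_catalogue
        g.property_catalogue |= self.property_catalogue
        return g

    def isa_digraph(self) -> nx.DiGraph:
        """The ``is_a`` edge set as a child -> parent directed graph."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self._concepts)
        for c in self:
            for p in c.parents:
                dg.add_edge(c.id, p)
        return dg


def ancestors(graph: ConceptGraph, concept_id: str) -> List[str]:
    """All concepts reachable from ``concept_id`` along ``is_a`` edges.

    Breadth-first order from the concept, lexicographic tie-break among
    parents discovered at the same depth; each ancestor listed exactly once;
    the concept itself excluded.  Deterministic for reproducible matching.
    """
    start = graph[concept_id]  # raises UnknownConceptError on bad id
    seen: set[str] = {start.id}
    order: List[str] = []
    queue: deque[str] = deque([start.id])
    while queue:
        current = queue.popleft()
        for parent in sorted(graph[current].parents):
            if parent not in seen:
                seen.add(parent)
                order.append(parent)
                queue.append(parent)
    return order


def assert_dag(graph: ConceptGraph) -> None:
    """Verify the ``is_a`` edges are acyclic; raise :class:`DagError` if not.

    On failure the error carries one offending cycle as a node list.
    """
    dg = graph.isa_digraph()
    try:
        cycle_edges = nx.find_cycle(dg)
    except nx.NetworkXNoCycle:
        return
    raise DagError([u for u, _v in cycle_edges])


def is_dag(graph: ConceptGraph) -> bool:
    """Verdict form of :func:`assert_dag`."""
    try:
        assert_dag(graph)
    except DagError:
        return False
    return True
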