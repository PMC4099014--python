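"""Grow a backbone ontology with entities imported from an aligned source.

For every aligned pair the source concept's properties and relationships
are merged onto its backbone equivalent, and the source concept's direct
and indirect descendants are imported as new backbone concepts.  Imported
concepts keep their original ids and names unchanged (the convention for
importing external ontology terms); direct children of an aligned source
concept are re-rooted under the backbone equivalent, deeper descendants
under their imported parent.  Relation targets pointing at aligned source
concepts are rewritten to the backbone equivalent.  Source concepts
outside all aligned subtrees are not imported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import networkx as nx

from .clustering import Alignment
from .model import Concept, ConceptGraph, assert_dag

__all__ = ["AugmentationReport", "augment"]


@dataclass
class AugmentationReport:
    """Tally of one augmentation run.

    ``properties_added`` and ``relationships_added`` count names newly
    introduced into the backbone's catalogues; ``conflicts`` lists source
    concepts (or relation targets) that could not be carried over.
    """

    concepts_added: int = 0
    properties_added: int = 0
    relationships_added: int = 0
    conflicts: List[Tuple[str, str]] = field(default_factory=list)


def _descendants(graph: ConceptGraph, concept_id: str) -> Set[str]:
    # is_a digraph points child -> parent, so descendants are the nodes
    # from which the concept is reachable.
    return nx.ancestors(graph.isa_digraph(), concept_id)


def augment(
    backbone: ConceptGraph,
    source: ConceptGraph,
    alignment: Alignment,
) -> Tuple[ConceptGraph, AugmentationReport]:
    """Merge aligned concepts and import their descendant subtrees.

    Alignment pairs are (backbone id, source id).  Returns the augmented
    graph (the backbone is not modified in place) and a report.
    """
    assert_dag(backbone)
    assert_dag(source)
    # aligned source concept -> backbone equivalent
    equivalent: Dict[str, str] = {}
    for pair in alignment:
        if pair.source not in backbone:
            raise KeyError(f"aligned id {pair.source!r} not in backbone")
        if pair.target not in source:
            raise KeyError(f"aligned id {pair.target!r} not in source")
        equivalent[pair.target] = pair.source

    result = backbone.copy()
    report = AugmentationReport()
    props_before = set(result.property_catalogue)
    rels_before = set(result.relationship_catalogue)

    # Candidate imports: all descendants of aligned source concepts that are
    # not themselves aligned, in topological order (parents first).
    candidates: Set[str] = set()
    for s in equivalent:
        candidates |= _descendants(source, s)
    candidates -= set(equivalent)

    order = [
        cid
        for cid in reversed(list(nx.topological_sort(source.isa_digraph())))
        if cid in candidates
    ]

    # Pass 1: decide which candidates can actually be imported.
    imported: Set[str] = set()
    for cid in order:
        if cid in backbone:
            report.conflicts.append(
                (cid, "id collides with an existing backbone concept")
            )
            continue
        surviving_parents = [
            p
            for p in source[cid].parents
            if p in equivalent or p in imported
        ]
        if not surviving_parents:
            report.conflicts.append(
                (cid, "no importable parent survives; concept orphaned")
            )
            continue
        imported.add(cid)

    def rewrite_target(owner: str, target: str) -> str | None:
        if target in equivalent:
            return equivalent[target]
        if target in imported:
            return target
        if target in backbone:
            return target
        report.conflicts.append(
            (owner, f"relation target {target!r} outside the import scope")
        )
        return None

    # Pass 2: import concepts with rewired parents and rewritten relations.
    for cid in order:
        if cid not in imported:
            continue
        src = source[cid].copy()
        src.parents = sorted(
            {equivalent.get(p, p) for p in source[cid].parents
             if p in equivalent or p in imported}
        )
        relations: Dict[str, List[str]] = {}
        for rel, targets in src.relations.items():
            kept = []
            for t in targets:
                rewritten = rewrite_target(cid, t)
                if rewritten is not None and rewritten not in kept:
                    kept.append(rewritten)
            if kept:
                relations[rel] = kept
        src.relations = relations
        result.add(src)
        report.concepts_added += 1

    # Merge aligned concepts: union of properties and relation entries.
    for s_id, b_id in sorted(equivalent.items()):
        s_concept = source[s_id]
        b_concept = result[b_id]
        for prop in s_concept.properties:
            if prop not in b_concept.properties:
                b_concept.properties.append(prop)
            result.property_catalogue.add(prop)
        for rel, targets in s_concept.relations.items():
            kept = b_concept.relations.setdefault(rel, [])
            for t in targets:
                rewritten = rewrite_target(s_id, t)
                if rewritten is not None and rewritten not in kept:
                    kept.append(rewritten)
            if not kept:
                del b_concept.relations[rel]
            result.relationship_catalogue.add(rel)

    for cid in imported:
        result.property_catalogue.update(result[cid].properties)
        result.relationship_catalogue.update(result[cid].relations)

    report.properties_added = len(result.property_catalogue - props_before)
    report.relationships_added = len(result.relationship_catalogue - rels_before)

    result.validate()
    return result, report
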