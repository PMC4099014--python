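"""Shared fixtures: tiny hand-built graphs and published alignment counts."""

from __future__ import annotations

import pytest

from ontoalign.model import Concept, ConceptGraph

# The six published pairwise alignment experiments: training-set size, the
# raw counts (n1 output pairs, n2 correct, n3 missed) and the printed
# percentage values of the four quality measures.
ALIGNMENT_EXPERIMENTS = {
    "GRO+SBO": dict(
        n_train=5, n1=51, n2=41, n3=11,
        precision=80.39, recall=78.85, f_measure=79.61, overall=59.62,
    ),
    "GRO+TarBase": dict(
        n_train=2, n1=6, n2=5, n3=2,
        precision=83.33, recall=71.43, f_measure=76.92, overall=57.14,
    ),
    "SBO+TarBase": dict(
        n_train=2, n1=7, n2=5, n3=3,
        precision=71.43, recall=62.50, f_measure=66.67, overall=37.50,
    ),
    "GRO+Backbone": dict(
        n_train=5, n1=39, n2=33, n3=8,
        precision=84.62, recall=80.49, f_measure=82.50, overall=65.85,
    ),
    "SBO+Backbone": dict(
        n_train=4, n1=27, n2=21, n3=5,
        precision=77.78, recall=80.77, f_measure=79.25, overall=57.69,
    ),
    "TarBase+Backbone": dict(
        n_train=3, n1=56, n2=49, n3=9,
        precision=87.50, recall=84.48, f_measure=85.96, overall=72.41,
    ),
}


@pytest.fixture
def chain_graph() -> ConceptGraph:
    """z is_a y is_a x."""
    return ConceptGraph("chain", [
        Concept(id="T:x", name="x"),
        Concept(id="T:y", name="y", parents=["T:x"]),
        Concept(id="T:z", name="z", parents=["T:y"]),
    ])


@pytest.fixture
def diamond_graph() -> ConceptGraph:
    """z is_a {y1, y2}; y1, y2 is_a x."""
    return ConceptGraph("diamond", [
        Concept(id="T:x", name="x"),
        Concept(id="T:y1", name="y1", parents=["T:x"]),
        Concept(id="T:y2", name="y2", parents=["T:x"]),
        Concept(id="T:z", name="z", parents=["T:y1", "T:y2"]),
    ])


@pytest.fixture
def mir_graph() -> ConceptGraph:
    """A miniature miR-flavoured ontology exercising every concept field."""
    return ConceptGraph("mir", [
        Concept(id="M:0001", name="entity"),
        Concept(id="M:0002", name="continuant", parents=["M:0001"]),
        Concept(
            id="M:0003",
            name="miRNA",
            synonyms=["microRNA"],
            definition="a short non-coding RNA",
            properties=["cellLines", "chromosomeLocation"],
            parents=["M:0002"],
            relations={"hasBinding": ["M:0004"]},
        ),
        Concept(id="M:0004", name="bindingSite", parents=["M:0002"]),
        Concept(
            id="M:0005",
            name="targetGene",
            properties=["miRNATargetGeneSymbol"],
            parents=["M:0002"],
            instances=["BRCA1"],
        ),
    ])
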