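"""Seeded generator of ontology pairs with known gold correspondences.

The generator emulates the situation the aligner is built for: two
schema-level ontologies — tens to hundreds of concepts arranged in a
rooted ``is_a`` DAG, carrying property lists and ``hasBinding``-style
relationship targets — that share a subset of concepts.  The shared subset
is copied into the second ontology under a fresh namespace and perturbed
at controlled rates: names receive character edits or are swapped for
lexicon synonyms, properties are dropped, and ``is_a`` edges are rewired.
The second ontology is padded with distractor concepts drawn from a
disjoint vocabulary so that gold recoverability stays controllable.

Everything is driven by one pseudo-random stream keyed on the seed, so a
configuration reproduces byte-identical ontologies, gold standard and
lexicon on every run.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from typing import List, Tuple

from .lexical import SynonymLexicon, name_similarity, normalize
from .model import Concept, ConceptGraph

__all__ = ["SynthConfig", "generate_pair", "training_subset"]

# Property-name pool shared by both ontologies; overlap in property names is
# what the property aspect has to work with.
_PROPERTY_POOL = [
    "cellLines",
    "chromosomeLocation",
    "miRNATargetSequence",
    "miRNATargetGeneSymbol",
    "miRNATargetCompleteName",
    "organism",
    "tissueType",
    "expressionLevel",
    "validationMethod",
    "publicationReference",
    "sequenceLength",
    "strandOrientation",
    "conservationScore",
    "bindingEnergy",
    "seedRegion",
    "geneFamily",
    "pathwayMembership",
    "diseaseAssociation",
    "regulationDirection",
    "experimentalEvidence",
]

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass
class SynthConfig:
    """Knobs of the synthetic ontology-pair generator.

    Defaults describe a mid-sized alignment problem: 50 concepts per
    ontology, half of them shared, every concept carrying 1-3 properties
    and a binding-site link (so all four similarity aspects are
    exercised), and mild perturbation of the shared copies.
    """

    n_concepts: int = 50
    overlap_fraction: float = 0.5
    name_perturb_rate: float = 0.1
    synonym_swap_rate: float = 0.05
    property_drop_rate: float = 0.1
    structure_rewire_rate: float = 0.1
    n_properties_per_concept: Tuple[int, int] = (1, 3)
    binding_density: float = 1.0
    confuser_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_concepts < 2:
            raise ValueError("n_concepts must be at least 2")
        for name in (
            "overlap_fraction",
            "name_perturb_rate",
            "synonym_swap_rate",
            "property_drop_rate",
            "structure_rewire_rate",
            "binding_density",
            "confuser_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.n_properties_per_concept
        if lo < 0 or hi < lo:
            raise ValueError("n_properties_per_concept must be a valid range")
        k = round(self.overlap_fraction * self.n_concepts)
        if k > self.n_concepts:
            raise ValueError("overlap larger than the graph is infeasible")


def _fresh_word(rng: random.Random, taken_norms: List[str]) -> str:
    """A pronounceable word lexically far (similarity < 0.5) from all taken."""
    for _attempt in range(200):
        n_syllables = rng.randint(3, 4)
        word = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
            for _ in range(n_syllables)
        )
        if all(name_similarity(word, t) < 0.5 for t in taken_norms):
            taken_norms.append(normalize(word))
            return word
    raise RuntimeError("could not draw a sufficiently distinct name")


def _perturb_name(rng: random.Random, name: str) -> str:
    """Substitute one random character."""
    pos = rng.randrange(len(name))
    alphabet = string.ascii_lowercase
    replacement = rng.choice([c for c in alphabet if c != name[pos]])
    return name[:pos] + replacement + name[pos + 1 :]


def generate_pair(
    cfg: SynthConfig,
) -> Tuple[ConceptGraph, ConceptGraph, List[Tuple[str, str]], SynonymLexicon]:
    """Generate two ontologies, their gold correspondences and a lexicon.

    The first ontology has exactly ``n_concepts`` concepts in namespace
    ``A``.  An upward-closed overlap subset (the first concepts in
    topological order, so ``is_a`` ancestry survives the copy) is copied
    into namespace ``B``, perturbed, and padded with distractors back up
    to ``n_concepts``.  Gold pairs map each copied concept to its origin.
    """
    rng = random.Random(cfg.seed)
    n = cfg.n_concepts
    k = max(2, round(cfg.overlap_fraction * n))
    k = min(k, n)

    taken: List[str] = []
    names = [_fresh_word(rng, taken) for _ in range(n)]
    lo, hi = cfg.n_properties_per_concept

    # --- ontology A: rooted DAG, index i's parents all have lower index ---
    parents_a: List[List[int]] = [[]]
    for i in range(1, n):
        n_parents = 2 if (i >= 2 and rng.random() < 0.2) else 1
        parents_a.append(sorted(rng.sample(range(i), n_parents)))
    properties_a = [
        sorted(rng.sample(_PROPERTY_POOL, rng.randint(lo, min(hi, len(_PROPERTY_POOL)))))
        for _ in range(n)
    ]
    bindings_a: List[List[int]] = []
    for i in range(n):
        if cfg.binding_density > 0 and rng.random() < cfg.binding_density:
            # Root binds forward to index 1; everyone else binds backwards,
            # so bindings of the overlap subset stay inside the subset.
            bindings_a.append([1 if i == 0 else rng.randrange(i)])
        else:
            bindings_a.append([])

    def aid(i: int) -> str:
        return f"A:{i:04d}"

    def bid(i: int) -> str:
        return f"B:{i:04d}"

    graph_a = ConceptGraph(name="synthetic-A")
    for i in range(n):
        graph_a.add(
            Concept(
                id=aid(i),
                name=names[i],
                properties=list(properties_a[i]),
                parents=[aid(p) for p in parents_a[i]],
                relations={"hasBinding": [aid(t) for t in bindings_a[i]]}
                if bindings_a[i]
                else {},
            )
        )
    graph_a.validate()

    # --- ontology B: perturbed copies of the overlap subset --------------
    synsets: List[List[str]] = []
    graph_b = ConceptGraph(name="synthetic-B")
    for i in range(k):
        name = names[i]
        if rng.random() < cfg.synonym_swap_rate:
            alt = _fresh_word(rng, taken)
            synsets.append([name, alt])
            name = alt
        elif rng.random() < cfg.name_perturb_rate:
            name = _perturb_name(rng, name)
        props = [
            p for p in properties_a[i] if rng.random() >= cfg.property_drop_rate
        ]
        my_parents = list(parents_a[i])
        if i >= 1 and rng.random() < cfg.structure_rewire_rate:
            my_parents = [rng.randrange(i)]
        bindings = [t for t in bindings_a[i] if t < k]
        graph_b.add(
            Concept(
                id=bid(i),
                name=name,
                properties=props,
                parents=[bid(p) for p in my_parents],
                relations={"hasBinding": [bid(t) for t in bindings]}
                if bindings
                else {},
            )
        )

    # --- distractors ------------------------------------------------------
    # A confuser is a homonym of a shared concept: it carries the shared
    # concept's original label, parents and properties while denoting a
    # different entity.  Such lexically identical but non-equivalent terms
    # are what make real alignment problems ambiguous; when the true copy
    # was perturbed, the homonym outranks it and gives weight learning a
    # persistent error signal.
    for i in range(k, n):
        if rng.random() < cfg.confuser_rate:
            t = rng.randrange(k)
            name = names[t]
            props = list(properties_a[t])
            my_parents = [bid(p) for p in parents_a[t]]
        else:
            name = _fresh_word(rng, taken)
            n_props = rng.randint(lo, min(hi, len(_PROPERTY_POOL)))
            props = sorted(rng.sample(_PROPERTY_POOL, n_props))
            my_parents = [bid(rng.randrange(i))]
        relations = {}
        if cfg.binding_density > 0 and rng.random() < cfg.binding_density:
            relations["hasBinding"] = [bid(rng.randrange(i))]
        graph_b.add(
            Concept(
                id=bid(i),
                name=name,
                properties=props,
                parents=my_parents,
                relations=relations,
            )
        )
    graph_b.validate()

    gold = [(aid(i), bid(i)) for i in range(k)]
    return graph_a, graph_b, gold, SynonymLexicon(synsets)


def training_subset(
    gold: List[Tuple[str, str]], n_examples: int, seed: int
) -> List[Tuple[str, str]]:
    """A seeded expert sample of the gold standard to train weights on."""
    if n_examples > len(gold):
        raise ValueError("cannot sample more training pairs than gold pairs")
    rng = random.Random(seed)
    return sorted(rng.sample(gold, n_examples))
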