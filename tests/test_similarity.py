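"""The four aspect measures, weighted aggregation and the all-pairs matrix."""

import itertools

import numpy as np
import pytest

from ontoalign.lexical import SynonymLexicon, name_similarity
from ontoalign.model import Concept, ConceptGraph
from ontoalign.similarity import (
    DEFAULT_THETA_MATCH,
    UNIFORM_WEIGHTS,
    WeightVector,
    binding_similarity,
    build_matrix,
    greedy_match,
    isa_similarity,
    overall_similarity,
    property_similarity,
    similarity_vector,
)
from ontoalign.synth import SynthConfig, generate_pair


def greedy_oracle(names_a, names_b, lexicon=None, floor=0.0):
    """All outcomes of exhaustively enumerated maximal-first merge orders.

    At every step all pairs attaining the current maximum admissible
    similarity are branched on; returns the set of final matchings (as
    frozensets of index pairs).
    """
    sims = {
        (i, j): name_similarity(a, b, lexicon)
        for i, a in enumerate(names_a)
        for j, b in enumerate(names_b)
    }

    def step(used_a, used_b, acc, outcomes):
        admissible = {
            (i, j): s for (i, j), s in sims.items()
            if s >= floor and i not in used_a and j not in used_b
        }
        if not admissible:
            outcomes.add(frozenset(acc))
            return
        best = max(admissible.values())
        for (i, j), s in admissible.items():
            if s == best:
                step(used_a | {i}, used_b | {j}, acc + [(i, j)], outcomes)

    outcomes: set = set()
    step(set(), set(), [], outcomes)
    return outcomes


class TestGreedyMatch:
    def test_never_reuses_an_element(self):
        matched = greedy_match(["a", "ab", "abc"], ["a", "ab"])
        assert len({i for i, _, _ in matched}) == len(matched)
        assert len({j for _, j, _ in matched}) == len(matched)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_merge_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        words = ["ka", "kab", "robu", "zintu", "zinu", "lor", "loru", "m"]
        a = list(rng.choice(words, size=4, replace=False))
        b = list(rng.choice(words, size=4, replace=False))
        ours = frozenset((i, j) for i, j, _ in greedy_match(a, b, floor=0.5))
        assert ours in greedy_oracle(a, b, floor=0.5)


class TestPropertySimilarity:
    def test_both_empty_is_zero(self):
        assert property_similarity([], []) == 0.0

    def test_identical_lists_are_one(self):
        props = ["cellLines", "chromosomeLocation"]
        assert property_similarity(props, props) == 1.0

    def test_dice_fraction(self):
        # one match out of lists of sizes 2 and 1 -> 2*1/3
        got = property_similarity(
            ["cellLines", "chromosomeLocation"], ["cellLines"], theta_match=0.9
        )
        assert got == pytest.approx(2 / 3)

    def test_near_matches_below_theta_do_not_count(self):
        assert property_similarity(["cellLines"], ["cellLinx"], theta_match=1.0) == 0.0


class TestIsaSimilarity:
    def test_two_roots_are_one(self, mir_graph):
        g2 = mir_graph.copy()
        assert isa_similarity(mir_graph, g2, "M:0001", "M:0001") == 1.0

    def test_identical_chains_are_one(self, mir_graph):
        g2 = mir_graph.copy()
        assert isa_similarity(mir_graph, g2, "M:0003", "M:0003") == 1.0

    def test_depth_mismatch_dilutes(self):
        g1 = ConceptGraph("a", [
            Concept(id="X:1", name="entity"),
            Concept(id="X:2", name="continuant", parents=["X:1"]),
            Concept(id="X:3", name="thing", parents=["X:2"]),
        ])
        g2 = ConceptGraph("b", [
            Concept(id="Y:1", name="entity"),
            Concept(id="Y:3", name="thing", parents=["Y:1"]),
        ])
        # ancestors {entity, continuant} vs {entity}: one perfect match / max(2,1)
        assert isa_similarity(g1, g2, "X:3", "Y:3") == pytest.approx(0.5)

    def test_root_vs_non_root_is_zero(self, mir_graph):
        g2 = mir_graph.copy()
        assert isa_similarity(mir_graph, g2, "M:0001", "M:0002") == 0.0


class TestBindingSimilarity:
    def test_no_targets_is_zero(self, mir_graph):
        g2 = mir_graph.copy()
        assert binding_similarity(mir_graph, g2, "M:0001", "M:0001") == 0.0

    def test_identical_targets_are_one(self, mir_graph):
        g2 = mir_graph.copy()
        assert binding_similarity(mir_graph, g2, "M:0003", "M:0003") == 1.0

    def test_dice_fraction(self):
        def graph(ns, bindings):
            concepts = [Concept(id=f"{ns}:s{i}", name=f"site{i}") for i in (1, 2)]
            concepts.append(Concept(
                id=f"{ns}:m", name="mir",
                relations={"hasBinding": [f"{ns}:s{i}" for i in bindings]},
            ))
            return ConceptGraph(ns, concepts)

        g1 = graph("A", [1, 2])
        g2 = graph("B", [1])
        got = binding_similarity(g1, g2, "A:m", "B:m", theta_match=0.9)
        assert got == pytest.approx(2 / 3)


class TestSimilarityVectorAndOverall:
    def test_self_comparison(self, mir_graph):
        g2 = mir_graph.copy()
        v = similarity_vector(mir_graph, g2, "M:0003", "M:0003")
        assert (v.s1_name, v.s2_properties, v.s3_isa, v.s4_binding) == (1, 1, 1, 1)
        # a concept without properties or bindings scores 0 on those aspects
        v_root = similarity_vector(mir_graph, g2, "M:0001", "M:0001")
        assert (v_root.s1_name, v_root.s2_properties) == (1, 0)
        assert (v_root.s3_isa, v_root.s4_binding) == (1, 0)

    def test_component_recomputation(self, mir_graph):
        g2 = mir_graph.copy()
        v = similarity_vector(mir_graph, g2, "M:0003", "M:0005")
        assert v.s1_name == name_similarity("miRNA", "targetGene")
        assert v.s2_properties == property_similarity(
            ["cellLines", "chromosomeLocation"], ["miRNATargetGeneSymbol"]
        )
        assert v.s3_isa == isa_similarity(mir_graph, g2, "M:0003", "M:0005")
        assert v.s4_binding == binding_similarity(mir_graph, g2, "M:0003", "M:0005")

    def test_overall_is_dot_product(self):
        from ontoalign.similarity import SimilarityVector

        v = SimilarityVector(1, 0, 0, 0)
        w = WeightVector(0.38, 0.15, 0.13, 0.34)
        assert overall_similarity(v, w) == pytest.approx(0.38)
        v2 = SimilarityVector(0.5, 1, 0.5, 1)
        w2 = WeightVector(0.65, 0.00, 0.35, 0.00)
        assert overall_similarity(v2, w2) == pytest.approx(0.50)
        assert overall_similarity(SimilarityVector(1, 1, 1, 1), UNIFORM_WEIGHTS) == 1.0

    def test_off_simplex_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            WeightVector(-0.5, 0.5, 0.5, 0.5)


class TestBuildMatrix:
    def test_one_by_one(self):
        g1 = ConceptGraph("a", [Concept(id="A:1", name="mirna")])
        g2 = ConceptGraph("b", [Concept(id="B:1", name="mirna")])
        m = build_matrix(g1, g2)
        assert m.overall.shape == (1, 1)
        assert m.overall[0, 0] == pytest.approx(0.5)  # name + ancestry only

    def test_empty_graph_rejected(self):
        g1 = ConceptGraph("a", [Concept(id="A:1", name="x")])
        with pytest.raises(ValueError):
            build_matrix(g1, ConceptGraph("empty"))

    def test_self_alignment_diagonal_dominates_rows(self):
        g1, _, _, _ = generate_pair(SynthConfig(n_concepts=5, seed=11))
        m = build_matrix(g1, g1.copy())
        for i in range(len(m.row_ids)):
            assert m.overall[i, i] >= m.overall[i, :].max() - 1e-12

    def test_reweight_matches_fresh_recomputation(self, mir_graph):
        g2 = mir_graph.copy()
        m = build_matrix(mir_graph, g2)
        w = WeightVector(0.4, 0.3, 0.2, 0.1)
        m.reweight(w)
        fresh = build_matrix(mir_graph, g2, w)
        assert np.allclose(m.overall, fresh.overall)
        assert np.allclose(m.overall, m.components @ w.as_array())

    @pytest.mark.parametrize("seed", [0, 1])
    def test_symmetry_and_bounds_on_synthetic_pairs(self, seed):
        cfg = SynthConfig(n_concepts=8, overlap_fraction=0.5, seed=seed)
        g1, g2, _, lex = generate_pair(cfg)
        m12 = build_matrix(g1, g2, UNIFORM_WEIGHTS, lex)
        m21 = build_matrix(g2, g1, UNIFORM_WEIGHTS, lex)
        assert np.all(m12.components >= 0) and np.all(m12.components <= 1)
        assert np.all(m12.overall >= 0) and np.all(m12.overall <= 1)
        assert np.allclose(m12.components, np.swapaxes(m21.components, 0, 1))
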