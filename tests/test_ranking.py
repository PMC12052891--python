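"""Edge weights, effective resistance, scoring, and ranking order."""

import math
import random
from dataclasses import replace

import pytest

from aopkg.fixtures import CCL2, CELLULAR_RESPONSE_TO_LIPID, random_instance
from aopkg.kg_store import Edge, OMNICORP_SOURCE
from aopkg.omnicorp import augment
from aopkg.ranking import (
    INFINITE_RESISTANCE,
    RankingConfig,
    ResistanceNetwork,
    answer_network,
    edge_weight,
    effective_resistance,
    rank,
    score_answer,
)
from aopkg.reasoner import match
from oracles import grounded_resistance

CFG = RankingConfig()


def curated(n_pubs: int, strength=None) -> Edge:
    return Edge("e", "A:1", "A:2", "related_to", "src:x",
                publications=frozenset(f"P:{i}" for i in range(n_pubs)),
                strength=strength)


def omnicorp(n_pubs: int) -> Edge:
    return Edge("e", "A:1", "A:2", "occurs_together_in_literature_with",
                OMNICORP_SOURCE,
                publications=frozenset(f"P:{i}" for i in range(n_pubs)))


class TestEdgeWeight:
    def test_baseline_applies_to_unreferenced_curated_edges(self):
        assert edge_weight(curated(0), CFG) == pytest.approx(1 - math.exp(-CFG.alpha))

    @pytest.mark.parametrize("n", [1, 2, 5, 20])
    def test_curated_outweighs_omnicorp_at_equal_support(self, n):
        assert edge_weight(curated(n), CFG) > edge_weight(omnicorp(n), CFG)

    def test_strictly_increasing_and_bounded(self):
        weights = [edge_weight(curated(n), CFG) for n in range(1, 60)]
        assert all(b > a for a, b in zip(weights, weights[1:]))
        assert all(0 < w < 1 for w in weights)
        assert weights[-1] > 0.999  # saturates toward 1

    def test_strength_attribute_overrides_counts(self):
        assert edge_weight(curated(12, strength=0.25), CFG) == 0.25

    def test_alpha_must_exceed_beta(self):
        with pytest.raises(ValueError, match="alpha > beta"):
            RankingConfig(alpha=0.1, beta=0.5)
        with pytest.raises(ValueError):
            RankingConfig(alpha=0.5, beta=0.0)


def net(links, s="a", t="z"):
    vertices = tuple(sorted({v for link in links for v in link[:2]}))
    return ResistanceNetwork(vertices, tuple(links), (s, t))


class TestEffectiveResistance:
    def test_single_edge_is_ohmic(self):
        assert effective_resistance(net([("a", "z", 0.4)])) == pytest.approx(2.5)

    def test_parallel_conductances_add(self):
        r = effective_resistance(net([("a", "z", 0.4), ("a", "z", 0.1)]))
        assert r == pytest.approx(1 / 0.5, rel=1e-12)

    def test_series_resistances_add(self):
        r = effective_resistance(net([("a", "m", 0.5), ("m", "z", 0.25)]))
        assert r == pytest.approx(1 / 0.5 + 1 / 0.25, rel=1e-12)

    def test_wheatstone_bridge_against_linear_solve(self):
        links = [("a", "b", 1.0), ("a", "c", 2.0), ("b", "c", 3.0),
                 ("b", "z", 4.0), ("c", "z", 5.0)]
        got = effective_resistance(net(links))
        assert got == pytest.approx(
            grounded_resistance(("a", "b", "c", "z"), links, "a", "z"), rel=1e-12
        )

    def test_disconnected_terminals_signal_infinity(self):
        r = effective_resistance(net([("a", "b", 1.0), ("y", "z", 1.0)]))
        assert r is INFINITE_RESISTANCE

    @pytest.mark.parametrize("seed", range(30))
    def test_random_networks_match_current_injection_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 12)
        vertices = tuple(f"v{i}" for i in range(n))
        # random spanning tree guarantees connectivity, then extra links
        links = [
            (vertices[i], vertices[rng.randrange(i)], rng.uniform(0.05, 1.0))
            for i in range(1, n)
        ]
        links += [
            (vertices[rng.randrange(n)], vertices[rng.randrange(n)], rng.uniform(0.05, 1.0))
            for _ in range(rng.randint(0, 2 * n))
        ]
        s, t = rng.sample(vertices, 2)
        network = ResistanceNetwork(vertices, tuple(links), (s, t))
        assert effective_resistance(network) == pytest.approx(
            grounded_resistance(vertices, links, s, t), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_rayleigh_monotonicity_under_edge_addition(self, seed):
        rng = random.Random(seed + 500)
        n = rng.randint(3, 10)
        vertices = tuple(f"v{i}" for i in range(n))
        links = [
            (vertices[i], vertices[rng.randrange(i)], rng.uniform(0.05, 1.0))
            for i in range(1, n)
        ]
        s, t = rng.sample(vertices, 2)
        base = effective_resistance(ResistanceNetwork(vertices, tuple(links), (s, t)))
        for _ in range(5):
            u, v = rng.sample(vertices, 2)
            more = links + [(u, v, rng.uniform(0.05, 1.0))]
            r = effective_resistance(ResistanceNetwork(vertices, tuple(more), (s, t)))
            assert r <= base + 1e-12


@pytest.fixture
def scored_answers(bundle):
    q = bundle.queries["table1_genes"]
    answers = match(q, bundle.kg)
    for a in answers:
        augment(a, bundle.corpus)
    return q, answers


class TestScoring:
    def test_single_curated_edge_score_closed_form(self, hierarchies):
        from aopkg.query_model import QueryEdge, QueryGraph, QueryNode
        from aopkg.reasoner import AnswerSubgraph

        q = QueryGraph(
            (QueryNode("n0", pinned_curie="A:1"), QueryNode("n1", pinned_curie="A:2")),
            (QueryEdge("e0", "n0", "n1"),),
        )
        a = AnswerSubgraph({"n0": "A:1", "n1": "A:2"}, {"e0": [curated(1)]})
        assert score_answer(a, q, CFG) == pytest.approx(1 - math.exp(-CFG.alpha))

    def test_fixture_answer_matches_series_parallel_closed_form(self, bundle, scored_answers):
        """The case-study answer network reduces by series/parallel laws:
        chain hops 2-4 in series, in parallel with the gene-phenotype
        literature shortcut, in series with hop 1, in parallel with the
        chemical-phenotype literature shortcut."""
        q, answers = scored_answers
        a = next(x for x in answers if x.node_bindings["n3"] == CCL2)
        netw = answer_network(a, q, CFG)
        conductance: dict[frozenset, float] = {}
        for u, v, w in netw.links:
            conductance[frozenset((u, v))] = conductance.get(frozenset((u, v)), 0.0) + w
        c, p, o, l, h = (a.node_bindings[f"n{i}"] for i in range(5))
        r_chain = (1 / conductance[frozenset((p, o))]
                   + 1 / conductance[frozenset((o, l))]
                   + 1 / conductance[frozenset((l, h))])
        r_inner = 1 / (1 / r_chain + conductance[frozenset((p, h))])
        r_upper = 1 / conductance[frozenset((c, p))] + r_inner
        r_total = 1 / (1 / r_upper + conductance[frozenset((c, h))])
        assert effective_resistance(netw) == pytest.approx(r_total, rel=1e-9)
        assert score_answer(a, q, CFG) == pytest.approx(1 / r_total, rel=1e-9)

    def test_adding_a_publication_strictly_increases_score(self, scored_answers):
        q, answers = scored_answers
        a = answers[0]
        base = score_answer(a, q, CFG)
        eid = sorted(a.edge_bindings)[0]
        richer = a.edge_bindings[eid][0]
        enriched = replace(
            richer, publications=richer.publications | {"PMID:EXTRA"}
        )
        a.edge_bindings[eid][0] = enriched
        a.score = None
        assert score_answer(a, q, CFG) > base

    def test_curated_to_omnicorp_downgrade_never_raises_score(self, scored_answers):
        q, answers = scored_answers
        for a in answers[:3]:
            base = score_answer(a, q, CFG)
            eid = sorted(a.edge_bindings)[0]
            e = a.edge_bindings[eid][0]
            pubs = e.publications or frozenset({"P:1"})
            downgraded = replace(
                e, predicate="occurs_together_in_literature_with",
                primary_source=OMNICORP_SOURCE, publications=pubs,
            )
            a.edge_bindings[eid][0] = downgraded
            a.score = None
            assert score_answer(a, q, CFG) <= base + 1e-12
            a.edge_bindings[eid][0] = e
            a.score = None

    def test_disconnected_network_scores_zero(self):
        from aopkg.query_model import QueryEdge, QueryGraph, QueryNode
        from aopkg.reasoner import AnswerSubgraph

        q = QueryGraph(
            (QueryNode("n0", pinned_curie="A:1"), QueryNode("n1", pinned_curie="A:2")),
            (QueryEdge("e0", "n0", "n1"),),
        )
        a = AnswerSubgraph({"n0": "A:1", "n1": "A:2"},
                           {"e0": [curated(1, strength=-1.0)]})  # nonpositive conductance
        assert score_answer(a, q, CFG) == 0.0


class TestRank:
    def test_descending_scores_with_lexicographic_ties(self, scored_answers):
        q, answers = scored_answers
        ranked = rank(answers, q, CFG)
        for a, b in zip(ranked, ranked[1:]):
            assert a.score >= b.score
            if a.score == b.score:
                assert a.binding_tuple(q) <= b.binding_tuple(q)

    def test_extra_publication_ranks_first(self, bundle):
        q = bundle.queries["table1_genes"]
        first = match(q, bundle.kg)
        second = match(q, bundle.kg)
        a0, b0 = first[0], second[0]
        eid = sorted(a0.edge_bindings)[0]
        e = a0.edge_bindings[eid][0]
        a0.edge_bindings[eid][0] = replace(
            e, publications=e.publications | {"PMID:MORE"}
        )
        ranked = rank([a0, b0], q, CFG)
        assert ranked[0] is a0

    @pytest.mark.parametrize("seed", range(8))
    def test_order_agrees_with_independent_rescoring(self, seed):
        g, q, corpus = random_instance(seed, n_nodes=12, n_hops=2)
        answers = match(q, g)
        for a in answers:
            augment(a, corpus)
        ranked = rank(answers, q, CFG)
        rescored = []
        for a in ranked:
            netw = answer_network(a, q, CFG)
            r = grounded_resistance(netw.vertices, netw.links, *netw.terminals) \
                if not math.isinf(effective_resistance(netw)) else math.inf
            rescored.append(0.0 if math.isinf(r) else 1 / r)
        assert all(
            x >= y - 1e-9 for x, y in zip(rescored, rescored[1:])
        )
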