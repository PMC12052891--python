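"""The matching engine.

``match`` finds every way of binding the query path's nodes to KG nodes such
that pinned nodes agree by CURIE, categorical nodes carry a category at or
below the query category, and every consecutive pair is joined by at least
one KG edge whose predicate descends from the query-edge predicate in an
admissible orientation (symmetric constraints accept either stored
orientation; directional ones require agreement or the registered inverse).

Answers are grouped by node-binding tuple: one answer per distinct tuple,
carrying the *complete* bundle of qualifying parallel edges for each query
edge — an answer's first hop may hold half a dozen predicates from as many
sources.  Matching is injective (distinct query nodes bind distinct CURIEs),
which rules out degenerate chemical-gene-chemical loops.

The algorithm is plain backtracking along the query path with adjacency
pruning; desk-scale graphs need nothing cleverer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kg_store import Edge, KnowledgeGraph
from .query_model import QueryGraph, QueryNode


@dataclass
class AnswerSubgraph:
    """One match: node bindings plus all qualifying KG edges per query edge."""

    node_bindings: dict[str, str]
    edge_bindings: dict[str, list[Edge]]
    augmentation_edges: list[Edge] = field(default_factory=list)
    score: float | None = None

    def binding_tuple(self, q: QueryGraph) -> tuple[str, ...]:
        return tuple(self.node_bindings[qid] for qid in q.path_qids)

    def bound_curies(self) -> list[str]:
        return sorted(set(self.node_bindings.values()))

    def all_bound_edges(self) -> list[Edge]:
        out: list[Edge] = []
        seen: set[str] = set()
        for eid in sorted(self.edge_bindings):
            for e in self.edge_bindings[eid]:
                if e.edge_id not in seen:
                    seen.add(e.edge_id)
                    out.append(e)
        return out


def candidate_nodes(g: KnowledgeGraph, qn: QueryNode) -> set[str]:
    """CURIEs that can bind a query node: singleton for pinned, category
    closure for categorical; a pinned CURIE absent from the graph gives an
    empty set rather than an error."""
    if qn.pinned_curie is not None:
        if qn.pinned_curie not in g.nodes:
            return set()
        if qn.category is not None:
            allowed = g.categories.descendants(qn.category)
            node = g.nodes[qn.pinned_curie]
            if not any(cat in allowed for cat in node.categories):
                return set()
        return {qn.pinned_curie}
    return g.nodes_with_category_under(qn.category)


def _hop_bundle(g: KnowledgeGraph, q: QueryGraph, qid_a: str, qid_b: str,
                cur_a: str, cur_b: str) -> list[Edge]:
    """Qualifying edges for the query edge joining qid_a/qid_b, with the
    constraint oriented as stored on the query edge."""
    qe = q.edge_between(qid_a, qid_b)
    s_cur = cur_a if qe.subject_qid == qid_a else cur_b
    o_cur = cur_b if qe.subject_qid == qid_a else cur_a
    return [
        e
        for e in sorted(
            (g.edges[eid] for eid in g._by_pair.get(frozenset((cur_a, cur_b)), ())),
            key=lambda e: e.edge_id,
        )
        if g.edge_qualifies(e, s_cur, o_cur, qe.predicate)
    ]


def match(q: QueryGraph, g: KnowledgeGraph) -> list[AnswerSubgraph]:
    """All answer subgraphs, in lexicographic order of their binding tuples."""
    order = q.path_qids
    candidates = {qid: sorted(candidate_nodes(g, q.node(qid))) for qid in order}
    answers: list[AnswerSubgraph] = []

    def extend(pos: int, bound: list[str], bundles: dict[str, list[Edge]]) -> None:
        if pos == len(order):
            answers.append(
                AnswerSubgraph(
                    node_bindings=dict(zip(order, bound)),
                    edge_bindings=dict(bundles),
                )
            )
            return
        qid = order[pos]
        if pos == 0:
            pool = candidates[qid]
        else:
            prev_cur = bound[-1]
            pool = [c for c in candidates[qid] if c in g.neighbors(prev_cur)]
        for cur in pool:
            if cur in bound:  # injective matching
                continue
            if pos > 0:
                qe = q.edge_between(order[pos - 1], qid)
                bundle = _hop_bundle(g, q, order[pos - 1], qid, bound[-1], cur)
                if not bundle:
                    continue
                bundles[qe.eid] = bundle
            bound.append(cur)
            extend(pos + 1, bound, bundles)
            bound.pop()
            if pos > 0:
                bundles.pop(q.edge_between(order[pos - 1], qid).eid, None)

    extend(0, [], {})
    answers.sort(key=lambda a: a.binding_tuple(q))
    return answers
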