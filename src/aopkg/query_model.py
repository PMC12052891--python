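"""Question topologies: path-shaped query graphs and their JSON dialect.

A query graph holds query nodes — *pinned* to a CURIE, constrained to a
node category, or both — and query edges carrying a single predicate
constraint (default ``related_to``, the predicate root, which matches
everything).  This package restricts topologies to simple paths of 1-6 hops
(a single pinned node with no edges is allowed as a degenerate query): the
adverse-outcome-pathway questions it targets are chains from an exposure to
an outcome, and a path makes the ranking terminals (first and last node)
well defined.

JSON dialect::

    {"nodes": {qid: {"ids": [curie], "categories": [name]}},
     "edges": {eid: {"subject": qid, "object": qid, "predicates": [name]}}}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .biolink_model import CategoryHierarchy, PredicateHierarchy
from .errors import BindingError, NameResolutionError, TopologyError
from .normalization import SynonymCliqueTable, normalize

MAX_HOPS = 6


@dataclass(frozen=True)
class QueryNode:
    qid: str
    pinned_curie: str | None = None
    category: str | None = None

    def __post_init__(self):
        if self.pinned_curie is None and self.category is None:
            raise TopologyError(f"query node {self.qid}: needs a pinned CURIE or a category")


@dataclass(frozen=True)
class QueryEdge:
    eid: str
    subject_qid: str
    object_qid: str
    predicate: str = "related_to"


@dataclass(frozen=True)
class QueryGraph:
    query_nodes: tuple[QueryNode, ...]
    query_edges: tuple[QueryEdge, ...]
    path_qids: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "path_qids", _validate_path(self))

    def node(self, qid: str) -> QueryNode:
        for qn in self.query_nodes:
            if qn.qid == qid:
                return qn
        raise KeyError(qid)

    def edge_between(self, qid_a: str, qid_b: str) -> QueryEdge:
        for qe in self.query_edges:
            if {qe.subject_qid, qe.object_qid} == {qid_a, qid_b}:
                return qe
        raise KeyError((qid_a, qid_b))


def _validate_path(q: QueryGraph) -> tuple[str, ...]:
    """Check the simple-path invariant and return qids in path order.

    The path starts at whichever endpoint is listed first among the query
    nodes, which keeps traversal (and ranking terminals) deterministic.
    """
    qids = [qn.qid for qn in q.query_nodes]
    if len(set(qids)) != len(qids):
        raise TopologyError("duplicate query-node ids")
    if not qids:
        raise TopologyError("query graph has no nodes")
    adjacency: dict[str, set[str]] = {qid: set() for qid in qids}
    for qe in q.query_edges:
        for endpoint in (qe.subject_qid, qe.object_qid):
            if endpoint not in adjacency:
                raise TopologyError(f"query edge {qe.eid}: unknown endpoint {endpoint!r}")
        if qe.subject_qid == qe.object_qid:
            raise TopologyError(f"query edge {qe.eid}: self-loop")
        if qe.object_qid in adjacency[qe.subject_qid]:
            raise TopologyError(f"parallel query edges between {qe.subject_qid}/{qe.object_qid}")
        adjacency[qe.subject_qid].add(qe.object_qid)
        adjacency[qe.object_qid].add(qe.subject_qid)
    if len(qids) == 1 and not q.query_edges:
        return tuple(qids)
    if len(q.query_edges) != len(qids) - 1:
        raise TopologyError("query graph must be a simple path (|edges| = |nodes| - 1)")
    if len(q.query_edges) > MAX_HOPS:
        raise TopologyError(f"query paths are limited to {MAX_HOPS} hops")
    degrees = {qid: len(n) for qid, n in adjacency.items()}
    ends = [qid for qid in qids if degrees[qid] == 1]
    if len(ends) != 2 or any(d > 2 for d in degrees.values()):
        raise TopologyError("query graph must be a simple path")
    order = [ends[0]]
    seen = {ends[0]}
    while len(order) < len(qids):
        nxt = [n for n in adjacency[order[-1]] if n not in seen]
        if not nxt:
            raise TopologyError("query graph is disconnected")
        order.append(nxt[0])
        seen.add(nxt[0])
    return tuple(order)


def parse_query(
    document: str,
    categories: CategoryHierarchy,
    predicates: PredicateHierarchy,
    cliques: SynonymCliqueTable | None = None,
) -> QueryGraph:
    """Parse and validate the JSON dialect; pinned CURIEs are normalized."""
    doc = json.loads(document)
    qnodes = []
    for qid, spec in doc.get("nodes", {}).items():
        ids = spec.get("ids") or []
        if len(ids) > 1:
            raise TopologyError(f"query node {qid}: at most one pinned CURIE is supported")
        cats = spec.get("categories") or []
        if len(cats) > 1:
            raise TopologyError(f"query node {qid}: at most one category is supported")
        category = cats[0] if cats else None
        if category is not None and category not in categories.members:
            raise NameResolutionError(f"query node {qid}: unknown category {category!r}")
        pinned = normalize(ids[0], cliques) if ids else None
        qnodes.append(QueryNode(qid, pinned_curie=pinned, category=category))
    qedges = []
    for eid, spec in doc.get("edges", {}).items():
        preds = spec.get("predicates") or ["related_to"]
        if len(preds) != 1:
            raise TopologyError(f"query edge {eid}: exactly one predicate is supported")
        if preds[0] not in predicates.members:
            raise NameResolutionError(f"query edge {eid}: unknown predicate {preds[0]!r}")
        qedges.append(QueryEdge(eid, spec["subject"], spec["object"], preds[0]))
    return QueryGraph(tuple(qnodes), tuple(qedges))


def serialize_query(q: QueryGraph) -> str:
    doc = {
        "nodes": {
            qn.qid: {
                **({"ids": [qn.pinned_curie]} if qn.pinned_curie else {}),
                **({"categories": [qn.category]} if qn.category else {}),
            }
            for qn in q.query_nodes
        },
        "edges": {
            qe.eid: {
                "subject": qe.subject_qid,
                "object": qe.object_qid,
                "predicates": [qe.predicate],
            }
            for qe in q.query_edges
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True)


# -- built-in AOP templates ---------------------------------------------------

#: slot name -> (qid, category) per template, in path order
_TEMPLATES = {
    "aop_chem_gene_process_gene_phenotype": (
        ("chemical", "n0", "ChemicalEntity"),
        ("gene1", "n1", "GeneOrProtein"),
        ("process", "n2", "BiologicalProcessOrActivity"),
        ("gene2", "n3", "GeneOrProtein"),
        ("phenotype", "n4", "PhenotypicFeature"),
    ),
    "aop_chem_gene_phenotype": (
        ("chemical", "n0", "ChemicalEntity"),
        ("gene", "n1", "GeneOrProtein"),
        ("phenotype", "n2", "PhenotypicFeature"),
    ),
}

#: slots that must be pinned when the template is instantiated
_REQUIRED = {"chemical", "phenotype"}


def builtin_template(name: str, bindings: dict[str, str]) -> QueryGraph:
    """Instantiate a packaged adverse-outcome-pathway query template.

    ``bindings`` pins template slots to CURIEs; the chemical and phenotype
    endpoints are mandatory, intermediate slots optional.
    """
    if name not in _TEMPLATES:
        raise BindingError(f"unknown template {name!r}; known: {sorted(_TEMPLATES)}")
    slots = _TEMPLATES[name]
    slot_names = {slot for slot, _, _ in slots}
    missing = _REQUIRED - set(bindings)
    if missing:
        raise BindingError(f"template {name}: missing bindings for {sorted(missing)}")
    unknown = set(bindings) - slot_names
    if unknown:
        raise BindingError(f"template {name}: unknown slots {sorted(unknown)}")
    qnodes = [
        QueryNode(qid, pinned_curie=bindings.get(slot), category=category)
        for slot, qid, category in slots
    ]
    qedges = [
        QueryEdge(f"e{i}", slots[i][1], slots[i + 1][1]) for i in range(len(slots) - 1)
    ]
    return QueryGraph(tuple(qnodes), tuple(qedges))
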