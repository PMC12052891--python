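"""Property-graph container: typed nodes and provenance-bearing multi-edges.

Edges are keyed by an explicit ``edge_id`` rather than by their
(subject, predicate, object) triple: two knowledge sources may assert the
same triple with different evidence, and both assertions must survive as
distinct records.  Publication support is stored as a set of opaque
identifiers; counts are always derived from the set, never stored.
Qualifiers are carried and serialized verbatim but never interpreted.

On-disk formats are KGX-style: a node TSV (id, name, category pipe-list) and
an edge TSV (id, subject, predicate, object, primary source, aggregator
pipe-list, publication pipe-list, qualifiers JSON), plus an equivalent
JSON-lines dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .biolink_model import CategoryHierarchy, PredicateHierarchy
from .errors import IntegrityError, NameResolutionError

#: primary source reserved for literature co-occurrence augmentation edges
OMNICORP_SOURCE = "omnicorp"
COOCCURRENCE_PREDICATE = "occurs_together_in_literature_with"

NODE_COLUMNS = ["id", "name", "category"]
EDGE_COLUMNS = [
    "id",
    "subject",
    "predicate",
    "object",
    "primary_knowledge_source",
    "aggregator_knowledge_sources",
    "publications",
    "qualifiers",
]


@dataclass(frozen=True)
class Node:
    curie: str
    name: str
    categories: tuple[str, ...]

    def __post_init__(self):
        if not self.categories:
            raise IntegrityError(f"node {self.curie} has no categories")


@dataclass(frozen=True)
class Edge:
    """One subject-predicate-object assertion with provenance.

    ``strength`` is an optional pre-computed conductance that, when present,
    overrides the publication-count weighting during ranking.
    """

    edge_id: str
    subject: str
    object: str
    predicate: str
    primary_source: str
    aggregator_sources: tuple[str, ...] = ()
    publications: frozenset[str] = frozenset()
    qualifiers: dict = field(default_factory=dict)
    strength: float | None = None

    @property
    def publication_count(self) -> int:
        return len(self.publications)

    def endpoints(self) -> frozenset[str]:
        return frozenset((self.subject, self.object))


class KnowledgeGraph:
    """Indexed multigraph of :class:`Node` and :class:`Edge` records."""

    def __init__(self, categories: CategoryHierarchy, predicates: PredicateHierarchy):
        self.categories = categories
        self.predicates = predicates
        self.nodes: dict[str, Node] = {}
        self.edges: dict[str, Edge] = {}
        self._by_pair: dict[frozenset[str], list[str]] = {}
        self._by_node: dict[str, list[str]] = {}
        self._by_predicate: dict[str, list[str]] = {}

    # -- construction -------------------------------------------------------

    def add_node(self, node: Node) -> None:
        if node.curie in self.nodes:
            raise IntegrityError(f"duplicate node curie: {node.curie}")
        for cat in node.categories:
            if cat not in self.categories.members:
                raise NameResolutionError(
                    f"node {node.curie}: unknown category {cat!r}"
                )
        self.nodes[node.curie] = node

    def add_edge(self, edge: Edge) -> None:
        if edge.edge_id in self.edges:
            raise IntegrityError(f"duplicate edge id: {edge.edge_id}")
        if edge.predicate not in self.predicates.members:
            raise NameResolutionError(
                f"edge {edge.edge_id}: unknown predicate {edge.predicate!r}"
            )
        missing = [c for c in (edge.subject, edge.object) if c not in self.nodes]
        if missing:
            raise IntegrityError(
                f"edge {edge.edge_id}: endpoint(s) not in graph: {', '.join(missing)}"
            )
        self.edges[edge.edge_id] = edge
        self._by_pair.setdefault(edge.endpoints(), []).append(edge.edge_id)
        self._by_node.setdefault(edge.subject, []).append(edge.edge_id)
        if edge.object != edge.subject:
            self._by_node.setdefault(edge.object, []).append(edge.edge_id)
        self._by_predicate.setdefault(edge.predicate, []).append(edge.edge_id)

    # -- queries ------------------------------------------------------------

    def neighbors(self, curie: str) -> set[str]:
        out = set()
        for eid in self._by_node.get(curie, ()):
            e = self.edges[eid]
            out.add(e.object if e.subject == curie else e.subject)
        return out

    def edge_qualifies(self, e: Edge, a: str, b: str, predicate_constraint: str) -> bool:
        """Does stored edge ``e`` satisfy constraint ``predicate_constraint``
        asked in orientation ``a`` -> ``b``?

        A symmetric constraint admits either stored orientation.  A
        directional constraint requires the stored orientation to agree, or
        the reverse orientation under the predicate's registered inverse.
        """
        if e.endpoints() != frozenset((a, b)):
            return False
        preds = self.predicates
        if preds.is_symmetric(predicate_constraint):
            return preds.is_descendant(e.predicate, predicate_constraint)
        if e.subject == a and e.object == b:
            if preds.is_descendant(e.predicate, predicate_constraint):
                return True
        if e.subject == b and e.object == a:
            if preds.is_symmetric(e.predicate):
                return preds.is_descendant(e.predicate, predicate_constraint)
            inv = preds.inverse(e.predicate)
            if inv is not None and preds.is_descendant(inv, predicate_constraint):
                return True
        return False

    def edges_between(self, a: str, b: str, predicate_constraint: str = "related_to") -> list[Edge]:
        """All edges joining ``a`` and ``b`` that satisfy the predicate
        constraint in admissible orientation, sorted by edge_id."""
        for curie in (a, b):
            if curie not in self.nodes:
                raise NameResolutionError(f"unknown curie: {curie}")
        hits = [
            self.edges[eid]
            for eid in self._by_pair.get(frozenset((a, b)), ())
            if self.edge_qualifies(self.edges[eid], a, b, predicate_constraint)
        ]
        return sorted(hits, key=lambda e: e.edge_id)

    def nodes_with_category_under(self, category: str) -> set[str]:
        allowed = self.categories.descendants(category)
        return {c for c, n in self.nodes.items() if any(cat in allowed for cat in n.categories)}

    # -- validation & equality ----------------------------------------------

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty when clean)."""
        problems = []
        for curie, node in self.nodes.items():
            for cat in node.categories:
                if cat not in self.categories.members:
                    problems.append(f"node {curie}: unknown category {cat!r}")
        for eid, e in self.edges.items():
            if e.predicate not in self.predicates.members:
                problems.append(f"edge {eid}: unknown predicate {e.predicate!r}")
            for endpoint in (e.subject, e.object):
                if endpoint not in self.nodes:
                    problems.append(f"edge {eid}: dangling endpoint {endpoint}")
            if e.primary_source == OMNICORP_SOURCE and e.predicate != COOCCURRENCE_PREDICATE:
                problems.append(
                    f"edge {eid}: omnicorp edges must use {COOCCURRENCE_PREDICATE}"
                )
        return problems

    def structurally_equal(self, other: "KnowledgeGraph") -> bool:
        return self.nodes == other.nodes and self.edges == other.edges

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph(self.categories, self.predicates)
        for node in self.nodes.values():
            g.add_node(node)
        for edge in self.edges.values():
            g.add_edge(edge)
        return g


# -- serialization -----------------------------------------------------------


def _split_pipe(cell: str) -> tuple[str, ...]:
    return tuple(x for x in str(cell).split("|") if x) if cell else ()


def node_to_record(n: Node) -> dict:
    return {"id": n.curie, "name": n.name, "category": list(n.categories)}


def edge_to_record(e: Edge) -> dict:
    rec = {
        "id": e.edge_id,
        "subject": e.subject,
        "predicate": e.predicate,
        "object": e.object,
        "primary_knowledge_source": e.primary_source,
        "aggregator_knowledge_sources": list(e.aggregator_sources),
        "publications": sorted(e.publications),
        "qualifiers": dict(sorted(e.qualifiers.items())),
    }
    if e.strength is not None:
        rec["strength"] = e.strength
    return rec


def _edge_from_record(rec: dict) -> Edge:
    return Edge(
        edge_id=rec["id"],
        subject=rec["subject"],
        object=rec["object"],
        predicate=rec["predicate"],
        primary_source=rec.get("primary_knowledge_source", ""),
        aggregator_sources=tuple(rec.get("aggregator_knowledge_sources", ())),
        publications=frozenset(rec.get("publications", ())),
        qualifiers=dict(rec.get("qualifiers", {})),
        strength=rec.get("strength"),
    )


def load_kg(
    node_table,
    edge_table,
    categories: CategoryHierarchy,
    predicates: PredicateHierarchy,
) -> KnowledgeGraph:
    """Load a graph from KGX-style node/edge tables (.tsv or .jsonl)."""
    node_table, edge_table = Path(node_table), Path(edge_table)
    g = KnowledgeGraph(categories, predicates)
    if node_table.suffix == ".jsonl":
        node_recs = [json.loads(line) for line in node_table.read_text().splitlines() if line]
        edge_recs = [json.loads(line) for line in edge_table.read_text().splitlines() if line]
    else:
        ndf = pd.read_csv(node_table, sep="\t", dtype=str, keep_default_na=False)
        edf = pd.read_csv(edge_table, sep="\t", dtype=str, keep_default_na=False)
        node_recs = [
            {"id": r["id"], "name": r["name"], "category": _split_pipe(r["category"])}
            for r in ndf.to_dict("records")
        ]
        edge_recs = []
        for r in edf.to_dict("records"):
            rec = dict(r)
            rec["aggregator_knowledge_sources"] = _split_pipe(r["aggregator_knowledge_sources"])
            rec["publications"] = _split_pipe(r["publications"])
            rec["qualifiers"] = json.loads(r["qualifiers"]) if r["qualifiers"] else {}
            if r.get("strength"):
                rec["strength"] = float(r["strength"])
            else:
                rec.pop("strength", None)
            edge_recs.append(rec)
    for rec in node_recs:
        g.add_node(Node(rec["id"], rec["name"], tuple(rec["category"])))
    dangling = [
        rec["id"]
        for rec in edge_recs
        if rec["subject"] not in g.nodes or rec["object"] not in g.nodes
    ]
    if dangling:
        raise IntegrityError(f"edges with dangling endpoints: {', '.join(sorted(dangling))}")
    for rec in edge_recs:
        g.add_edge(_edge_from_record(rec))
    return g


def save_kg(g: KnowledgeGraph, node_table, edge_table) -> None:
    """Write a graph to KGX-style tables; format chosen by extension."""
    node_table, edge_table = Path(node_table), Path(edge_table)
    node_recs = [node_to_record(g.nodes[c]) for c in sorted(g.nodes)]
    edge_recs = [edge_to_record(g.edges[e]) for e in sorted(g.edges)]
    if node_table.suffix == ".jsonl":
        node_table.write_text("".join(json.dumps(r, sort_keys=True) + "\n" for r in node_recs))
        edge_table.write_text("".join(json.dumps(r, sort_keys=True) + "\n" for r in edge_recs))
        return
    with open(node_table, "w") as fh:
        fh.write("\t".join(NODE_COLUMNS) + "\n")
        for r in node_recs:
            fh.write(f"{r['id']}\t{r['name']}\t{'|'.join(r['category'])}\n")
    with open(edge_table, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS + ["strength"]) + "\n")
        for r in edge_recs:
            fh.write(
                "\t".join(
                    [
                        r["id"],
                        r["subject"],
                        r["predicate"],
                        r["object"],
                        r["primary_knowledge_source"],
                        "|".join(r["aggregator_knowledge_sources"]),
                        "|".join(r["publications"]),
                        json.dumps(r["qualifiers"], sort_keys=True),
                        "" if "strength" not in r else repr(r["strength"]),
                    ]
                )
                + "\n"
            )


def relabel_edge(e: Edge, subject: str, object: str) -> Edge:
    """Edge with endpoints re-pointed (used by canonicalization)."""
    return replace(e, subject=subject, object=object)
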