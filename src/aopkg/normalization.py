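"""Synonym-clique node normalization.

A clique is an equivalence class of identifiers (CURIEs) plus display labels
for one real-world entity, with a single preferred CURIE.  ``normalize``
resolves any member CURIE or label to the preferred CURIE; a token in no
clique is returned unchanged, so the function is total.  Label lookup is a
case-insensitive exact match only — cliquing real vocabularies is an
offline job, this layer just resolves against a finished table.

``canonicalize_graph`` rewrites a graph onto preferred CURIEs, merging nodes
that fall into the same clique and re-pointing (never dropping) their edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import AmbiguityError, IntegrityError
from .kg_store import KnowledgeGraph, Node, relabel_edge


@dataclass(frozen=True)
class SynonymClique:
    preferred_curie: str
    preferred_label: str
    member_curies: frozenset[str]
    labels: frozenset[str]

    def __post_init__(self):
        if self.preferred_curie not in self.member_curies:
            raise IntegrityError(
                f"clique {self.preferred_curie}: preferred curie must be a member"
            )


@dataclass
class SynonymCliqueTable:
    """Disjoint cliques with reverse indexes from member CURIE and label."""

    cliques: list[SynonymClique]
    _by_curie: dict[str, SynonymClique] = field(init=False, repr=False)
    _by_label: dict[str, list[SynonymClique]] = field(init=False, repr=False)

    def __post_init__(self):
        self._by_curie = {}
        self._by_label = {}
        for clique in self.cliques:
            for curie in clique.member_curies:
                if curie in self._by_curie:
                    raise IntegrityError(f"curie {curie} belongs to two cliques")
                self._by_curie[curie] = clique
            for label in clique.labels:
                self._by_label.setdefault(label.casefold(), []).append(clique)

    def clique_of(self, token: str) -> SynonymClique | None:
        if token in self._by_curie:
            return self._by_curie[token]
        candidates = self._by_label.get(token.casefold(), [])
        if len(candidates) > 1:
            raise AmbiguityError(token, [c.preferred_curie for c in candidates])
        return candidates[0] if candidates else None


def normalize(token: str, table: SynonymCliqueTable | None) -> str:
    """Preferred CURIE of the clique containing ``token``; identity fallback."""
    if table is None:
        return token
    clique = table.clique_of(token)
    return clique.preferred_curie if clique is not None else token


def canonicalize_graph(g: KnowledgeGraph, table: SynonymCliqueTable | None) -> KnowledgeGraph:
    """Rewrite every node onto its preferred CURIE and merge synonym nodes.

    Merged nodes take the clique's preferred label and the union of member
    categories.  Every edge survives with endpoints re-pointed, so the edge
    count is conserved and the operation is idempotent.
    """
    if table is None:
        return g.copy()
    out = KnowledgeGraph(g.categories, g.predicates)
    merged: dict[str, Node] = {}
    for curie in sorted(g.nodes):
        node = g.nodes[curie]
        clique = table.clique_of(curie)
        target = clique.preferred_curie if clique else curie
        name = clique.preferred_label if clique else node.name
        if target in merged:
            prev = merged[target]
            cats = tuple(dict.fromkeys(prev.categories + node.categories))
            merged[target] = Node(target, prev.name, cats)
        else:
            merged[target] = Node(target, name, node.categories)
    for curie in sorted(merged):
        out.add_node(merged[curie])
    for eid in sorted(g.edges):
        e = g.edges[eid]
        out.add_edge(
            relabel_edge(e, normalize(e.subject, table), normalize(e.object, table))
        )
    return out


def load_clique_table(path) -> SynonymCliqueTable:
    """Read a (preferred_curie, member_curie, label) TSV, one row per member."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    cliques = []
    for preferred, grp in df.groupby("preferred_curie", sort=True):
        members = frozenset(grp["member_curie"])
        labels = frozenset(l for l in grp["label"] if l)
        pref_rows = grp[grp["member_curie"] == preferred]
        pref_label = pref_rows["label"].iloc[0] if len(pref_rows) else sorted(labels)[0]
        cliques.append(SynonymClique(str(preferred), pref_label, members, labels))
    return SynonymCliqueTable(cliques)


def save_clique_table(table: SynonymCliqueTable, path) -> None:
    rows = []
    for clique in sorted(table.cliques, key=lambda c: c.preferred_curie):
        label_by_member = {}
        # preferred member keeps the preferred label; others get a stable pick
        spare = sorted(clique.labels - {clique.preferred_label})
        for i, member in enumerate(sorted(clique.member_curies - {clique.preferred_curie})):
            label_by_member[member] = spare[i % len(spare)] if spare else clique.preferred_label
        label_by_member[clique.preferred_curie] = clique.preferred_label
        for member in sorted(clique.member_curies):
            rows.append((clique.preferred_curie, member, label_by_member[member]))
    with open(path, "w") as fh:
        fh.write("preferred_curie\tmember_curie\tlabel\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
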