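"""Literature co-occurrence evidence.

A :class:`CorpusIndex` maps each CURIE to the set of publications whose
abstracts mention it; the co-occurrence count of two entities is the size of
the intersection of their posting sets.  ``augment`` attaches one symmetric
``occurs_together_in_literature_with`` edge (primary source ``omnicorp``)
for every unordered pair of distinct bound nodes with a nonzero count —
including pairs that are not adjacent in the query, since literature support
between, say, a gene and the terminal phenotype is still evidence for the
answer.  Zero-count pairs contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from .kg_store import COOCCURRENCE_PREDICATE, OMNICORP_SOURCE, Edge
from .reasoner import AnswerSubgraph


@dataclass
class CorpusIndex:
    postings: dict[str, frozenset[str]] = field(default_factory=dict)

    def publications(self, curie: str) -> frozenset[str]:
        return self.postings.get(curie, frozenset())


def cooccurrence_count(index: CorpusIndex, a: str, b: str) -> int:
    """|postings[a] ∩ postings[b]|; symmetric, zero for unknown CURIEs."""
    return len(index.publications(a) & index.publications(b))


def cooccurrence_edge(index: CorpusIndex, a: str, b: str) -> Edge | None:
    """The augmentation edge for an unordered pair, or None if the pair
    never co-occurs.  Endpoints are stored in lexicographic order (the
    predicate is symmetric, so orientation is arbitrary but fixed)."""
    lo, hi = sorted((a, b))
    shared = index.publications(lo) & index.publications(hi)
    if not shared:
        return None
    return Edge(
        edge_id=f"omnicorp:{lo}--{hi}",
        subject=lo,
        object=hi,
        predicate=COOCCURRENCE_PREDICATE,
        primary_source=OMNICORP_SOURCE,
        publications=frozenset(shared),
    )


def augment(answer: AnswerSubgraph, index: CorpusIndex) -> AnswerSubgraph:
    """Attach co-occurrence edges for all co-occurring bound-node pairs.

    Existing bindings are untouched and re-augmenting is a no-op, so the
    operation is idempotent and insensitive to bound-node order.
    """
    present = {e.edge_id for e in answer.augmentation_edges}
    for a, b in combinations(answer.bound_curies(), 2):
        e = cooccurrence_edge(index, a, b)
        if e is not None and e.edge_id not in present:
            answer.augmentation_edges.append(e)
            present.add(e.edge_id)
    answer.augmentation_edges.sort(key=lambda e: e.edge_id)
    return answer


def load_corpus(path) -> CorpusIndex:
    """Read a two-column (curie, publication_id) TSV, one row per posting."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    postings: dict[str, set[str]] = {}
    for curie, pub in zip(df["curie"], df["publication_id"]):
        postings.setdefault(curie, set()).add(pub)
    return CorpusIndex({c: frozenset(p) for c, p in postings.items()})


def save_corpus(index: CorpusIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write("curie\tpublication_id\n")
        for curie in sorted(index.postings):
            for pub in sorted(index.postings[curie]):
                fh.write(f"{curie}\t{pub}\n")
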