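"""Miniature Biolink-style semantic layer.

Two rooted DAGs drive every matching decision in this package: the node
*category* hierarchy (rooted at ``NamedThing``) and the edge *predicate*
hierarchy (rooted at ``related_to``).  A query constraint names one member;
any descendant of that member satisfies the constraint, so querying with
``related_to`` returns every predicate in the graph while querying with
``increases_expression_of`` returns only that assertion.

Predicates additionally carry a symmetry flag (``related_to`` and
``occurs_together_in_literature_with`` are orderless; ``causes`` or
``increases_response_to`` are not) and an optional registered inverse
(``actively_involved_in`` / ``actively_involves``), both of which the matcher
consults when deciding whether a stored edge orientation is admissible.

The hierarchies ship as small curated TSV tables frozen into the package;
they approximate one Biolink release rather than tracking the live model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import IntegrityError, NameResolutionError

CATEGORY_ROOT = "NamedThing"
PREDICATE_ROOT = "related_to"


def _toposort_check_acyclic(members: frozenset[str], parents: dict[str, frozenset[str]]) -> None:
    # Kahn's algorithm over child->parent links; leftovers mean a cycle.
    out_deg = {m: len(parents.get(m, frozenset())) for m in members}
    ready = [m for m, d in out_deg.items() if d == 0]
    children: dict[str, list[str]] = {m: [] for m in members}
    for child, ps in parents.items():
        for p in ps:
            children[p].append(child)
    seen = 0
    while ready:
        node = ready.pop()
        seen += 1
        for c in children[node]:
            out_deg[c] -= 1
            if out_deg[c] == 0:
                ready.append(c)
    if seen != len(members):
        stuck = sorted(m for m, d in out_deg.items() if d > 0)
        raise IntegrityError(f"hierarchy contains a cycle through: {', '.join(stuck)}")


@dataclass(frozen=True)
class Hierarchy:
    """A rooted DAG of names with reachability ("is-a") queries.

    ``parent_links`` maps each non-root member to its parent set; every member
    must reach ``root``.  Reachability is reflexive: a name is its own
    descendant.
    """

    root: str
    parent_links: dict[str, frozenset[str]]
    members: frozenset[str] = field(init=False)

    def __post_init__(self):
        names = {self.root} | set(self.parent_links)
        for ps in self.parent_links.values():
            names |= set(ps)
        object.__setattr__(self, "members", frozenset(names))
        _toposort_check_acyclic(self.members, self.parent_links)
        for m in self.members:
            if m != self.root and not self._reaches_root(m):
                raise IntegrityError(f"{m!r} does not reach root {self.root!r}")
        object.__setattr__(self, "_ancestor_cache", {})

    def _reaches_root(self, name: str) -> bool:
        stack, seen = [name], set()
        while stack:
            cur = stack.pop()
            if cur == self.root:
                return True
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self.parent_links.get(cur, ()))
        return False

    def _require(self, name: str) -> None:
        if name not in self.members:
            raise NameResolutionError(f"unknown hierarchy member: {name!r}")

    def ancestors(self, name: str) -> frozenset[str]:
        """All names reachable from ``name`` by parent links, including itself."""
        self._require(name)
        cache: dict[str, frozenset[str]] = self.__dict__["_ancestor_cache"]
        if name not in cache:
            acc = {name}
            for p in self.parent_links.get(name, ()):
                acc |= self.ancestors(p)
            cache[name] = frozenset(acc)
        return cache[name]

    def is_descendant(self, child: str, ancestor: str) -> bool:
        """True iff ``ancestor`` lies in the reflexive ancestor closure of ``child``."""
        self._require(ancestor)
        return ancestor in self.ancestors(child)

    def descendants(self, ancestor: str) -> frozenset[str]:
        """Every member whose ancestor closure contains ``ancestor`` (itself included)."""
        self._require(ancestor)
        return frozenset(m for m in self.members if ancestor in self.ancestors(m))


class CategoryHierarchy(Hierarchy):
    def __init__(self, parent_links: dict[str, frozenset[str]]):
        super().__init__(root=CATEGORY_ROOT, parent_links=parent_links)


@dataclass(frozen=True)
class PredicateHierarchy(Hierarchy):
    """Predicate DAG plus per-predicate symmetry flags and inverse registry."""

    symmetric: frozenset[str] = frozenset()
    inverses: dict[str, str] = field(default_factory=dict)

    def __init__(
        self,
        parent_links: dict[str, frozenset[str]],
        symmetric: frozenset[str] = frozenset(),
        inverses: dict[str, str] | None = None,
    ):
        inv = dict(inverses or {})
        # registry is bidirectional: registering (a, b) also registers (b, a)
        for a, b in list(inv.items()):
            inv.setdefault(b, a)
        object.__setattr__(self, "symmetric", frozenset(symmetric))
        object.__setattr__(self, "inverses", inv)
        super().__init__(root=PREDICATE_ROOT, parent_links=parent_links)
        for p in self.symmetric:
            self._require(p)
        for a, b in self.inverses.items():
            self._require(a)
            self._require(b)
            if a in self.symmetric or b in self.symmetric:
                raise IntegrityError(f"symmetric predicate {a!r}/{b!r} cannot have an inverse")

    def is_symmetric(self, predicate: str) -> bool:
        self._require(predicate)
        return predicate in self.symmetric

    def inverse(self, predicate: str) -> str | None:
        """The registered inverse of ``predicate``, or None if none is registered."""
        self._require(predicate)
        return self.inverses.get(predicate)


def _read_pairs(path) -> list[tuple[str, str]]:
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise IntegrityError(f"expected two tab-separated columns in {path}: {line!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def _pairs_to_links(pairs: list[tuple[str, str]]) -> dict[str, frozenset[str]]:
    links: dict[str, set[str]] = {}
    for child, parent in pairs:
        links.setdefault(child, set()).add(parent)
    return {c: frozenset(ps) for c, ps in links.items()}


def load_category_hierarchy(path) -> CategoryHierarchy:
    """Read a two-column (child, parent) TSV into a CategoryHierarchy."""
    return CategoryHierarchy(_pairs_to_links(_read_pairs(path)))


def load_predicate_hierarchy(hierarchy_path, symmetric_path, inverse_path) -> PredicateHierarchy:
    """Read the predicate DAG, symmetric-predicate list, and inverse pairs."""
    symmetric = frozenset(
        line.strip()
        for line in Path(symmetric_path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
    inverses = dict(_read_pairs(inverse_path))
    return PredicateHierarchy(
        _pairs_to_links(_read_pairs(hierarchy_path)), symmetric=symmetric, inverses=inverses
    )


def default_hierarchies() -> tuple[CategoryHierarchy, PredicateHierarchy]:
    """The curated in-repo category and predicate tables."""
    data = resources.files("aopkg") / "data"
    with resources.as_file(data) as d:
        cats = load_category_hierarchy(d / "category_hierarchy.tsv")
        preds = load_predicate_hierarchy(
            d / "predicate_hierarchy.tsv",
            d / "symmetric_predicates.tsv",
            d / "inverse_predicates.tsv",
        )
    return cats, preds
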