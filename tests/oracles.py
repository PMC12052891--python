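"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closure caches, pair indexes, and
backtracking matcher: reachability is a plain DFS over the raw parent-link
dict, matching is exhaustive enumeration over node tuples, and effective
resistance is a grounded linear solve.  They are slow and simple on purpose.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def dfs_reachable(parent_links: dict, child: str, ancestor: str) -> bool:
    """Reflexive reachability by explicit depth-first search."""
    stack, seen = [child], set()
    while stack:
        cur = stack.pop()
        if cur == ancestor:
            return True
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(parent_links.get(cur, ()))
    return False


def oracle_edge_qualifies(preds, e, a: str, b: str, constraint: str) -> bool:
    """Spec semantics re-derived from the raw hierarchy tables."""
    if {e.subject, e.object} != {a, b} or a == b:
        return False
    links = preds.parent_links
    if constraint in preds.symmetric:
        return dfs_reachable(links, e.predicate, constraint)
    if (e.subject, e.object) == (a, b) and dfs_reachable(links, e.predicate, constraint):
        return True
    if (e.subject, e.object) == (b, a):
        if e.predicate in preds.symmetric and dfs_reachable(links, e.predicate, constraint):
            return True
        inv = preds.inverses.get(e.predicate)
        if inv is not None and dfs_reachable(links, inv, constraint):
            return True
    return False


def oracle_candidates(g, qn) -> list[str]:
    if qn.pinned_curie is not None:
        if qn.pinned_curie not in g.nodes:
            return []
        if qn.category is not None:
            node = g.nodes[qn.pinned_curie]
            if not any(
                dfs_reachable(g.categories.parent_links, c, qn.category)
                for c in node.categories
            ):
                return []
        return [qn.pinned_curie]
    return sorted(
        curie
        for curie, node in g.nodes.items()
        if any(
            dfs_reachable(g.categories.parent_links, c, qn.category)
            for c in node.categories
        )
    )


def brute_force_match(q, g) -> dict[tuple, dict[str, tuple]]:
    """Exhaustive enumeration over all candidate tuples.

    Returns {binding tuple (path order): {query edge id: tuple of edge ids}}.
    """
    order = q.path_qids
    cand = [oracle_candidates(g, q.node(qid)) for qid in order]
    all_edges = sorted(g.edges.values(), key=lambda e: e.edge_id)
    # per-hop map (bound a, bound b) -> bundle, from one linear scan per pair
    hop_edges: list[dict[tuple[str, str], tuple[str, ...]]] = []
    for a_qid, b_qid in zip(order, order[1:]):
        qe = q.edge_between(a_qid, b_qid)
        table: dict[tuple[str, str], tuple[str, ...]] = {}
        for a in cand[order.index(a_qid)]:
            for b in cand[order.index(b_qid)]:
                if a == b:
                    continue
                s, o = (a, b) if qe.subject_qid == a_qid else (b, a)
                bundle = tuple(
                    e.edge_id
                    for e in all_edges
                    if oracle_edge_qualifies(g.predicates, e, s, o, qe.predicate)
                )
                if bundle:
                    table[(a, b)] = bundle
        hop_edges.append(table)
    results = {}
    for tup in product(*cand):
        if len(set(tup)) != len(tup):
            continue
        bundles = {}
        ok = True
        for i, (a, b) in enumerate(zip(tup, tup[1:])):
            bundle = hop_edges[i].get((a, b))
            if bundle is None:
                ok = False
                break
            qe = q.edge_between(order[i], order[i + 1])
            bundles[qe.eid] = bundle
        if ok:
            results[tup] = bundles
    return results


def grounded_resistance(vertices, links, source: str, sink: str) -> float:
    """Effective resistance by grounding the sink and solving L'v = i."""
    index = {v: i for i, v in enumerate(vertices)}
    n = len(index)
    lap = np.zeros((n, n))
    for u, v, w in links:
        if u == v or w <= 0:
            continue
        i, j = index[u], index[v]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
    keep = [i for i in range(n) if i != index[sink]]
    reduced = lap[np.ix_(keep, keep)]
    rhs = np.zeros(n - 1)
    rhs[keep.index(index[source])] = 1.0
    potentials = np.linalg.solve(reduced, rhs)
    return float(potentials[keep.index(index[source])])
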