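"""Resistance-network answer scoring.

Each answer subgraph is treated as an electrical network: every bound KG
edge and every literature-co-occurrence edge becomes a conductor between its
endpoint nodes, and the answer's score is the reciprocal of the two-terminal
effective resistance between the bindings of the first and last query node.
Strong, well-evidenced chains conduct well and score high; thin chains score
low; a disconnected network has infinite resistance and scores zero.

Edge conductance saturates with publication support::

    w(e) = 1 - exp(-alpha * max(baseline, n_pubs))   curated / text-mined
    w(e) = 1 - exp(-beta  * n_pubs)                  co-occurrence (omnicorp)

with ``alpha > beta > 0`` so that a curated publication always counts for
more than a co-occurrence, and ``baseline`` (default 1) giving curated
assertions without listed publications the benefit of one.  The saturating
form keeps conductances in (0, 1), strictly increasing in support.  An edge
may instead carry an explicit pre-computed ``strength``, which is used
verbatim as its conductance.

Parallel edges between the same pair add their conductances; the effective
resistance is computed from the weighted graph Laplacian via its
pseudoinverse, which agrees with series/parallel reduction wherever the
network is series-parallel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kg_store import OMNICORP_SOURCE, Edge
from .query_model import QueryGraph
from .reasoner import AnswerSubgraph

#: distinguished return value for a network whose terminals are disconnected
INFINITE_RESISTANCE = math.inf


@dataclass(frozen=True)
class RankingConfig:
    """Scoring coefficients; ``alpha`` weighs curated publications,
    ``beta`` co-occurrence publications, per publication."""

    alpha: float = 0.5
    beta: float = 0.1
    baseline_curated_count: int = 1

    def __post_init__(self):
        if not (self.alpha > self.beta > 0):
            raise ValueError(
                f"curated weight must exceed co-occurrence weight: "
                f"need alpha > beta > 0, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.baseline_curated_count < 1:
            raise ValueError("baseline_curated_count must be >= 1")


@dataclass(frozen=True)
class ResistanceNetwork:
    vertices: tuple[str, ...]
    links: tuple[tuple[str, str, float], ...]  # (u, v, conductance)
    terminals: tuple[str, str]


def edge_weight(e: Edge, cfg: RankingConfig) -> float:
    """Conductance of one edge, in (0, 1)."""
    if e.strength is not None:
        return e.strength
    if e.primary_source == OMNICORP_SOURCE:
        n = e.publication_count
        coefficient = cfg.beta
    else:
        n = max(cfg.baseline_curated_count, e.publication_count)
        coefficient = cfg.alpha
    return 1.0 - math.exp(-coefficient * n)


def effective_resistance(net: ResistanceNetwork) -> float:
    """Two-terminal effective resistance of the weighted network.

    Computed as (e_s - e_t)^T L^+ (e_s - e_t) with L the weighted Laplacian
    (parallel conductances summed, self-loops ignored).  Returns
    :data:`INFINITE_RESISTANCE` when the terminals are not connected.
    """
    s, t = net.terminals
    if s == t:
        return 0.0
    index = {v: i for i, v in enumerate(net.vertices)}
    n = len(index)
    lap = np.zeros((n, n))
    adjacency: dict[str, set[str]] = {v: set() for v in net.vertices}
    for u, v, w in net.links:
        if u == v or w <= 0:
            continue
        i, j = index[u], index[v]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
        adjacency[u].add(v)
        adjacency[v].add(u)
    # terminal connectivity by BFS over nonzero links
    frontier, seen = [s], {s}
    while frontier:
        cur = frontier.pop()
        for nb in adjacency[cur]:
            if nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    if t not in seen:
        return INFINITE_RESISTANCE
    pinv = np.linalg.pinv(lap, hermitian=True)
    d = np.zeros(n)
    d[index[s]], d[index[t]] = 1.0, -1.0
    return float(d @ pinv @ d)


def answer_network(answer: AnswerSubgraph, q: QueryGraph, cfg: RankingConfig) -> ResistanceNetwork:
    """The resistance network over all bound and augmentation edges, with
    terminals at the first and last query-path bindings."""
    links = tuple(
        (e.subject, e.object, edge_weight(e, cfg))
        for e in answer.all_bound_edges() + list(answer.augmentation_edges)
    )
    vertices = tuple(answer.bound_curies())
    terminals = (
        answer.node_bindings[q.path_qids[0]],
        answer.node_bindings[q.path_qids[-1]],
    )
    return ResistanceNetwork(vertices, links, terminals)


def score_answer(answer: AnswerSubgraph, q: QueryGraph, cfg: RankingConfig | None = None) -> float:
    """1 / effective resistance; 0 for a disconnected network.  The score is
    stored on the answer and returned."""
    cfg = cfg or RankingConfig()
    r = effective_resistance(answer_network(answer, q, cfg))
    if math.isinf(r):
        answer.score = 0.0
    elif r == 0.0:  # degenerate single-node query: terminals coincide
        answer.score = math.inf
    else:
        answer.score = 1.0 / r
    return answer.score


def rank(
    answers: list[AnswerSubgraph], q: QueryGraph, cfg: RankingConfig | None = None
) -> list[AnswerSubgraph]:
    """Descending by score; ties broken lexicographically on binding tuple."""
    cfg = cfg or RankingConfig()
    for a in answers:
        if a.score is None:
            score_answer(a, q, cfg)
    return sorted(answers, key=lambda a: (-a.score, a.binding_tuple(q)))
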