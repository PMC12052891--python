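# Methods

## Problem setting

The package answers path-shaped questions over a typed biomedical property
graph. A query is a chain of 1–6 hops whose nodes are either *pinned* to a
specific entity (a CURIE such as `PUBCHEM.COMPOUND:2796`) or constrained to
a node category (such as `GeneOrProtein`), and whose edges carry a single
predicate constraint. The archetype is the adverse-outcome-pathway
template: chemical exposure → molecular target → key biological event →
effector gene → adverse phenotype. An *answer subgraph* is one way of
binding the query's nodes to graph entities, together with **all** graph
edges that support each hop and any literature co-occurrence edges between
bound entities.

## Semantic layer

Categories and predicates are members of two rooted DAGs (roots
`NamedThing` and `related_to`), shipped as curated TSV tables inside the
package. The tables approximate one release of the Biolink Model; they are
frozen rather than fetched so that every run is reproducible offline, and
they deliberately cover only the members the package's scope needs (about a
dozen of each). Multiple parents are allowed; reachability is computed with
memoized DFS and is reflexive, so every name is its own descendant.

A constraint names one member and admits its entire descendant set.
Predicates additionally carry:

- a **symmetry flag** — `related_to`, `associated_with`, `interacts_with`,
  and `occurs_together_in_literature_with` are orderless; everything else
  is directional;
- an optional **registered inverse** — an edge stored as
  (process, `actively_involves`, gene) satisfies a query asking
  (gene, `actively_involved_in`, process), because both spell the same
  assertion viewed from opposite sides.

## Matching

Matching is backtracking along the query path with candidate pruning by
adjacency. Bound nodes must be pairwise distinct (injective matching),
which excludes degenerate chemical–gene–chemical loops. For each hop the
answer carries the *complete* bundle of parallel qualifying edges — in the
case study the first hop holds seven edges across six predicates — so
answers are grouped one-per-node-binding-tuple. A stored edge qualifies for
a hop when its predicate descends from the hop's constraint and its
orientation is admissible: either orientation for a symmetric constraint;
for a directional constraint, stored orientation agreement, or the reverse
orientation under a registered inverse (or under a symmetric stored
predicate, which carries no orientation of its own). Output order is
lexicographic on binding tuples, making every downstream artifact
deterministic.

One consequence of grouping answers by node-binding tuple is that result
multiplicity counts parallel evidence once: a query whose free slot admits
12 entities yields exactly 12 answers here, even where a system that splits
answers per edge combination would report more. Distinct bound entities,
not subgraph multiplicity, are this package's unit of account.

## Normalization

Synonym cliques are disjoint sets of identifiers with one preferred CURIE
and a preferred label. `normalize` is total: member CURIEs and
(case-insensitively, exact-match) labels map to the preferred CURIE,
unknown tokens map to themselves, and a label shared by two cliques raises
an ambiguity error naming the candidates rather than guessing — the
case-study table contains two genuinely duplicated process labels, so this
path is exercised. Canonicalizing a graph rewrites every node onto its
preferred CURIE, merging synonym nodes (union of categories, preferred
label wins) and re-pointing their edges. No edge is ever dropped or
deduplicated, so edge count is conserved and the operation is idempotent.
Pipelines canonicalize both the graph and the query's pinned CURIEs before
matching.

## Literature co-occurrence

The corpus index maps each CURIE to the set of publications mentioning it;
the co-occurrence count of a pair is the size of the posting-set
intersection. After matching, every unordered pair of distinct bound nodes
with a nonzero count gains one `occurs_together_in_literature_with` edge
(primary source `omnicorp`) whose publication set is the intersection
itself. Augmentation covers *all* bound pairs, not only query-adjacent
ones: a shortcut between a mid-path gene and the terminal phenotype is
real evidence and materially changes the resistance network below.
Zero-count pairs contribute nothing, so an answer over k nodes gains
between 0 and k(k−1)/2 edges.

## Ranking

Each answer becomes a resistance network: vertices are the bound entities,
every bound or augmentation edge is a conductor, and the terminals are the
bindings of the first and last query-path node (the exposure and the
outcome — the question is the strength of *that* connection).

Edge conductance saturates with publication support:

    w(e) = 1 − exp(−α · max(baseline, n_pubs))   curated / text-mined
    w(e) = 1 − exp(−β · n_pubs)                  co-occurrence

Defaults: α = 0.5 per curated publication, β = 0.1 per co-occurrence,
baseline = 1. The exponential-saturation form and these constants are this
package's design choices; the governing contract is qualitative —
publication-weighted conductances, curated evidence weighted above
co-occurrence (enforced as α > β > 0 at construction), score inversely
related to network resistance — and all three constants are exposed in
`RankingConfig`, a JSON config file, and CLI flags. The per-publication
semantics of α means a 12-publication curated edge is effectively a unit
conductor, while a single co-occurrence contributes ≈ 0.095. An edge may
instead carry an explicit `strength` attribute (e.g. a precomputed
statistical weight), used verbatim as its conductance; no transformation
from p-values is defined.

Effective resistance is computed from the weighted graph Laplacian via its
Moore–Penrose pseudoinverse, R = (e_s − e_t)ᵀ L⁺ (e_s − e_t), with
parallel conductances summed and self-loops ignored. Terminals left
disconnected (possible only for degenerate inputs, since a matched path
always connects them) yield a distinguished infinite-resistance value and
score 0; a single-node query has coincident terminals, zero resistance,
and an infinite score. By Rayleigh monotonicity, adding any edge or any
publication can only lower resistance, so scores respond monotonically to
evidence — a property the test suite checks directly. Ranking is
descending by score with lexicographic tie-breaks on binding tuples;
scores are per-answer and never normalized across a result set.

## The case-study fixture

`build_case_study()` deterministically assembles a 46-node, 98-edge graph
for the clofibrate / PPARA / hepatic fibrosis question, along with synonym
cliques, a literature corpus, and three named queries. Its design targets
the worked answer's published totals — 22 edges = 16 curated + 6
co-occurrence; a 12-publication CTD edge; text-mined edges with 3 and 2
publications; co-occurrence counts of 4 (clofibrate–PPARA) and 8
(PPARA–hepatic fibrosis); 11 intermediary genes beyond CCL2; 30
intermediary processes beyond GO:0071396. Ten of the 16 curated edges are
attributed to the knowledge sources publicly documented for them (CTD,
DrugCentral, Drug Mechanism Database, Human Metabolome Database, Binding
Database, two Text Mining Provider edges, two Hetionet edges, one
DisGeNET-via-Pharos edge); the remaining six are *reconstructions*, needed
to reach the published total of 16 but unrecoverable individually, and are
explicitly attributed to the pseudo-source `fixture:unenumerated` so they
cannot be mistaken for real assertions. Corpus posting lists are built so
each co-occurring pair shares a dedicated publication block, which realizes
the target intersection counts exactly and guarantees every other pair
intersects empty. All publication identifiers are synthetic tokens
(`PMID:FIX…`, `PMID:OC…`).

What the fixture does **not** emulate: production scale (tens of millions
of edges), the full breadth of real knowledge sources and their conflicting
assertions, qualified-edge semantics (qualifiers are carried and serialized
but never interpreted in matching), and real literature frequencies. Tests
passing on the fixture therefore demonstrate the *semantics* — hierarchy
expansion, orientation rules, grouping, augmentation, scoring — not
robustness to real-world graph noise or scale.

`random_instance(seed, …)` generates property-test instances (≤ 50 nodes):
random typed nodes, noise edges, and a *planted* query path whose stored
edges are drawn from the query predicates' descendant sets in admissible
orientations, guaranteeing at least one match by construction. The matcher
is validated against exhaustive tuple enumeration on two hundred such
instances (8–16 nodes, 1–3 hops — sizes chosen to keep the exhaustive
oracle exact yet fast), and the resistance solver against a grounded
linear-solve oracle on random connected networks of ≤ 12 vertices.

## Numerical and formatting choices

- Floats in results files are serialized at 12 significant digits; with
  deterministic answer ordering this makes end-to-end result files
  byte-identical across runs, which the test suite asserts.
- Effective-resistance agreement with closed forms is tested at relative
  error 1e-9; `numpy.linalg.pinv` on ≤ 50-vertex Laplacians is far inside
  that tolerance.
- Ties in ranking, edge-bundle order, and answer order all break
  lexicographically; no step of the pipeline consults a random source.
- The run manifest written beside each results file records inputs, config,
  and a timestamp; the timestamp is confined to the manifest so the results
  file stays reproducible byte-for-byte.

## Known limitations

- Query topologies are restricted to simple paths (1–6 hops); branching or
  cyclic query graphs are rejected at validation. This keeps the ranking
  terminals well defined but is narrower than a full graph-pattern
  reasoner.
- Single-predicate constraints only; no predicate disjunctions and no
  qualifier constraints in queries.
- The frozen semantic tables cover the handful of categories and predicates
  the package's domain needs, not the full Biolink Model, and `Cell` is
  declared but unpopulated in the fixture.
- Gene/protein conflation is whatever the clique table says; the fixture
  treats PPARA as a single gene-or-protein entity.
- The scoring constants are defensible defaults, not fitted values;
  production systems derive edge weights from richer per-source metrics
  than publication counts.
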