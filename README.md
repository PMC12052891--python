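# aopkg

Desk-scale question answering over biomedical knowledge graphs: pose an
adverse-outcome-pathway-shaped path query ("chemical — gene or protein —
biological process — gene or protein — phenotype") against a Biolink-style
property graph, and get back ranked answer subgraphs with full evidence and
provenance.

It is aimed at toxicologists and computational biologists who want to probe
mechanistic hypotheses — e.g. *how might exposure to the PPARα agonist
clofibrate relate to hepatic fibrosis?* — on graphs they can hold in memory,
with semantics matching the large production knowledge-graph reasoners:

- **Hierarchy-aware matching.** Node categories and edge predicates live in
  rooted DAGs; a query constraint admits every descendant, so `related_to`
  (the predicate root) returns whatever more specific assertions exist.
  Symmetric predicates match in either stored orientation; directional ones
  require orientation agreement or a registered inverse
  (`actively_involved_in` / `actively_involves`).
- **Node normalization.** Synonym cliques map any member identifier or label
  to one preferred CURIE; graphs are canonicalized (synonym nodes merged,
  edges re-pointed) before matching.
- **Literature co-occurrence.** A corpus index maps CURIEs to publication
  sets; every pair of bound answer nodes that shares publications gains an
  `occurs_together_in_literature_with` evidence edge.
- **Resistance-network ranking.** Each answer subgraph becomes an electrical
  network: an edge with *n* supporting publications gets conductance
  `w = 1 − exp(−α·n)` (curated/text-mined, α = 0.5) or `1 − exp(−β·n)`
  (co-occurrence, β = 0.1, so curated evidence always counts for more).
  Parallel conductances add, and the answer score is
  `1 / R_eff(first query node, last query node)`, the reciprocal of the
  two-terminal effective resistance computed from the weighted graph
  Laplacian. Dense, well-evidenced chains conduct well and rank high.

## Worked example

The package ships a deterministic case-study knowledge graph (46 nodes,
98 edges) for the clofibrate → PPARA → hepatic fibrosis question, plus its
synonym cliques, literature corpus, and three canned queries:

```
aopkg fixture --out demo/kg
aopkg query --kg demo/kg --query demo/kg/queries/fig1b_full.json --out demo/results.json
```

`fig1b_full` pins clofibrate (`PUBCHEM.COMPOUND:2796`) and hepatic fibrosis
(`HP:0001395`) and leaves the three intermediate slots categorical. The run
returns 42 answer subgraphs; the top-ranked one binds PPARA
(`NCBIGene:5465`), "cellular response to lipid" (`GO:0071396`), and CCL2
(`NCBIGene:6347`):

```
NCBIGene:5465  GO:0071396  NCBIGene:6347   score 1.01590255745
NCBIGene:5465  GO:0071396  NCBIGene:1277   score 0.835814594636
NCBIGene:5465  GO:0071396  NCBIGene:4864   score 0.835814594636
...
```

That first answer carries 22 edges: 16 from curated or text-mined sources —
including a seven-edge first hop between clofibrate and PPARA spanning six
predicates (`affects`, `increases_expression_of`, `increases_activity_of`,
`increases_response_to`, `decreases_response_to`, `related_to`), with the
CTD edge alone holding 12 supporting publications — and 6 literature
co-occurrence edges, among them a shortcut directly linking PPARA to
hepatic fibrosis with 8 shared publications. The score 1.016 is the
reciprocal of the network's effective resistance between clofibrate and
hepatic fibrosis; the CCL2 answer wins because its hops are both thicker
(more parallel edges) and better referenced than its rivals'.

Pinning the process slot to `GO:0071396` (`table1_genes.json`) yields 12
distinct genes/proteins in the second gene slot; pinning the gene slots
instead (`table2_processes.json`) yields 31 distinct biological processes
or activities.

All of this is equally available as a library:

```python
from aopkg import build_case_study, match, augment, rank

bundle = build_case_study()
q = bundle.queries["fig1b_full"]
answers = match(q, bundle.kg)
for a in answers:
    augment(a, bundle.corpus)
best = rank(answers, q)[0]
print(best.node_bindings, round(best.score, 6))
```

## Layout

| module | what it does |
| --- | --- |
| `aopkg.biolink_model` | category/predicate DAGs, symmetry flags, inverses |
| `aopkg.kg_store` | the property-graph container and KGX-style TSV/JSONL IO |
| `aopkg.normalization` | synonym cliques, `normalize`, graph canonicalization |
| `aopkg.query_model` | path-query representation, JSON dialect, AOP templates |
| `aopkg.reasoner` | backtracking matcher producing answer subgraphs |
| `aopkg.omnicorp` | corpus index, co-occurrence counts, answer augmentation |
| `aopkg.ranking` | edge conductances, effective resistance, scoring, ranking |
| `aopkg.fixtures` | the case-study bundle and seeded random instances |
| `aopkg.cli` | `aopkg fixture / query / normalize / validate` |

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
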